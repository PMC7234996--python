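"""Calibration and operating-characteristic experiments for the PI-KW test.

These are the package's own validation studies, run on synthetic cohorts with
known ground truth:

* star-tree calibration — on a star phylogeny the tips are exchangeable, so
  the PI null must agree with both the chi-square(1) limit and a
  label-permutation null;
* type-I error — with no clade effect, the full stratified pipeline should
  reject about 5% of the time, while the conventional (naive) KW test is
  anti-conservative because related species are not independent;
* power — rejection frequency as a function of the clade shift, expressed in
  units of the root-to-tip Brownian standard deviation sqrt(sigma2 * depth);
* planted-motif recovery — the ARE scanner must find every planted consensus
  instance in generated promoters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .are_scan import ARE_CONSENSUS, count_ares
from .bm_sim import BMConfig, simulate_bm
from .cohort import assign_strata
from .npstats import empirical_percentile, kw_h_matrix
from .phylo import Node, TimeTree
from .pi_kw import run_pipeline
from .synthetic_data import SynthConfig, generate_promoters, make_dataset

__all__ = [
    "star_tree",
    "star_tree_thresholds",
    "RejectionRates",
    "null_rejection_rates",
    "power_curve",
    "planted_motif_recovery",
]


def star_tree(n_tips: int, depth: float = 1.0) -> TimeTree:
    """Star phylogeny: no shared internal edges, hence exchangeable tips."""
    root = Node(0.0, None, [Node(depth, f"s{i:03d}") for i in range(n_tips)])
    return TimeTree(root)


def star_tree_thresholds(
    n_tips: int = 200, n0: int = 60, n_sims: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """PI-null and label-permutation-null 95% thresholds on a star tree.

    Returns ``(pi_threshold, permutation_threshold)``. On a star tree both
    resampling schemes are exchangeable, so the two thresholds and the
    chi-square(1) 0.95 quantile (3.841) should agree up to Monte-Carlo error.
    """
    tree = star_tree(n_tips)
    labels = np.array([0] * n0 + [1] * (n_tips - n0))
    tm = simulate_bm(tree, BMConfig(n_reps=n_sims, seed=seed))
    pi_thr = empirical_percentile(kw_h_matrix(tm.values, labels), 95.0)

    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    observed = tm.values[:, 0]
    perm_h = np.empty(n_sims)
    for i in range(n_sims):
        perm_h[i] = kw_h_matrix(observed[:, None], rng.permutation(labels))[0]
    perm_thr = empirical_percentile(perm_h, 95.0)
    return float(pi_thr), float(perm_thr)


@dataclass
class RejectionRates:
    pi_rejections: int
    naive_rejections: int
    n_tests: int

    @property
    def pi_rate(self) -> float:
        return self.pi_rejections / self.n_tests

    @property
    def naive_rate(self) -> float:
        return self.naive_rejections / self.n_tests


def null_rejection_rates(
    n_datasets: int = 200,
    n_tips: int = 80,
    n_sims: int = 500,
    seed0: int = 0,
    stratify_edges: tuple = (20.0,),
    clade_shift: float = 0.0,
) -> RejectionRates:
    """Pooled per-stratum rejection rates of the full stratified pipeline.

    Dataset d uses seed ``seed0 + d``. Each dataset is stratified on the
    (independent) lifespan-like trait and every testable stratum contributes
    one PI-KW test and one conventional chi-square KW test to the pool.
    With ``clade_shift = 0`` the PI rate estimates the type-I error; the
    naive rate exposes the phylogenetic inflation of the conventional test.
    """
    pi = naive = n_tests = 0
    for d in range(n_datasets):
        cfg = SynthConfig(n_tips=n_tips, seed=seed0 + d, clade_shift=clade_shift)
        tree, table, _ = make_dataset(cfg)
        assignment = assign_strata(table, "max_lifespan", stratify_edges)
        summary, _ = run_pipeline(
            tree, table, "ms_bmr", assignment, n_sims=n_sims, seed=cfg.seed
        )
        tested = summary[summary.tested]
        n_tests += len(tested)
        pi += int(tested.significant.sum())
        naive += int((tested.chisq_p < 0.05).sum())
    return RejectionRates(pi, naive, n_tests)


def power_curve(
    shift_multipliers: tuple = (0.0, 0.5, 1.0, 2.0),
    n_datasets: int = 100,
    n_tips: int = 80,
    n_sims: int = 500,
    seed0: int = 5000,
) -> dict[float, float]:
    """PI-KW rejection frequency per clade-shift level (single stratum).

    Shifts are multiples of the root-to-tip BM standard deviation
    sqrt(sigma2 * depth). The same dataset seeds are reused across levels,
    pairing the comparisons so the monotonicity of power in effect size is
    assessed with reduced Monte-Carlo variance.
    """
    defaults = SynthConfig(n_tips=n_tips)
    sd = float(np.sqrt(defaults.sigma2_trait * defaults.tree_depth))
    rates: dict[float, float] = {}
    for mult in shift_multipliers:
        rej = n_tests = 0
        for d in range(n_datasets):
            cfg = SynthConfig(
                n_tips=n_tips, seed=seed0 + d, clade_shift=float(mult) * sd
            )
            tree, table, _ = make_dataset(cfg)
            assignment = assign_strata(table, "max_lifespan", (1e-9,))
            summary, _ = run_pipeline(
                tree, table, "ms_bmr", assignment, n_sims=n_sims, seed=cfg.seed
            )
            tested = summary[summary.tested]
            n_tests += len(tested)
            rej += int(tested.significant.sum())
        rates[float(mult)] = rej / n_tests
    return rates


def planted_motif_recovery(
    n_seqs: int = 8,
    length: int = 2000,
    planted_counts: tuple = (1, 2, 3, 2, 1, 3, 2, 1),
    gc: float = 0.5,
    seed: int = 0,
    window: int = 1000,
) -> float:
    """Fraction of planted ARE consensus instances the scanner recovers."""
    records, bed, truth = generate_promoters(
        n_seqs, length, planted_counts, gc, seed, window=window
    )
    table = count_ares(dict(records), bed, ARE_CONSENSUS, window=window)
    hits = {
        row.sequence_id: {(h.start, h.strand) for h in row.hits}
        for row in table.itertuples()
    }
    if not truth:
        return 1.0
    found = sum(
        (p["start"], p["strand"]) in hits[p["sequence_id"]] for p in truth
    )
    return found / len(truth)
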