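"""Phylogenetically independent Kruskal-Wallis (PI-KW) testing.

Per stratum, the engine first screens with a conventional KW test of the
response by KEAP1 functional status (chi-square tail), then assesses
significance against an empirical null built on the phylogeny: the tree is
pruned to exactly the stratum's species, replicate continuous characters are
simulated under Brownian motion on the pruned tree, and each replicate's H is
computed with the REAL factor labels and the SIMULATED character as the
response. The 95th nearest-rank percentile of that null is the significance
threshold; shared ancestry — a monophyletic factor in particular — inflates
the null well past the chi-square 3.841, which is exactly the
non-independence the procedure corrects for.

The factor labels are held fixed and only the trait is resampled, so the
simulated characters originate from the same phylogenetic positions as the
species tested. Each stratum draws from an RNG stream derived from
(master seed, stratum id), so adding strata never perturbs existing nulls.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .bm_sim import BMConfig, simulate_bm
from .cohort import StratumAssignment, check_balance
from .npstats import (
    EmpiricalNull,
    GroupedSample,
    KWResult,
    empirical_p,
    empirical_percentile,
    kruskal_wallis,
    kw_h_matrix,
)
from .phylo import TimeTree, prune_to

logger = logging.getLogger(__name__)

__all__ = [
    "PIKWResult",
    "stratum_seed",
    "conventional_screen",
    "run_pi_kw",
    "run_pipeline",
    "write_results",
]


@dataclass
class PIKWResult:
    stratum_id: str
    n_per_level: dict  # {"0": n0, "1": n1}
    observed_H: float
    chisq_p: float
    screened: bool
    null: EmpiricalNull
    threshold_95: float
    empirical_p_add_one: float
    empirical_p_raw: float
    significant: bool


def stratum_seed(master_seed: int, stratum_id: str) -> int:
    """Deterministic per-stratum seed from (master seed, stratum id).

    Uses SHA-256 of the stratum id (stable across processes, unlike hash()),
    folded with the master seed and reduced below 2^31.
    """
    digest = hashlib.sha256(stratum_id.encode("utf-8")).digest()
    token = int.from_bytes(digest[:8], "big")
    return int((master_seed * 0x9E3779B1 + token) % (2**31))


def conventional_screen(
    table: pd.DataFrame,
    assignment: StratumAssignment,
    response: str,
    alpha: float = 0.05,
) -> dict[str, tuple[Optional[KWResult], bool]]:
    """Conventional KW of the response by KEAP1 status within each bin.

    A stratum is screened (selected for PI analysis) iff its chi-square
    p-value is below alpha. Strata missing a factor level are skipped with a
    log entry and map to (None, False).
    """
    indexed = table.set_index("species")
    out: dict[str, tuple[Optional[KWResult], bool]] = {}
    for label in assignment.bin_labels:
        members = assignment.bins[assignment.bins == label].index
        if len(members) == 0:
            continue
        sub = indexed.loc[members]
        levels = sub["keap1_functional"].unique()
        if len(levels) < 2:
            logger.info("stratum %s missing a factor level; skipped", label)
            out[label] = (None, False)
            continue
        res = kruskal_wallis(
            GroupedSample(
                sub[response].to_numpy(), sub["keap1_functional"].to_numpy()
            )
        )
        out[label] = (res, res.chisq_p < alpha)
    return out


def run_pi_kw(
    tree: TimeTree,
    table: pd.DataFrame,
    assignment: StratumAssignment,
    stratum_id: str,
    response: str,
    n_sims: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> PIKWResult:
    """Run the PI-KW test for one stratum.

    Steps: prune the tree to the stratum's species; simulate ``n_sims``
    Brownian replicates on the pruned tree; compute the KW H of each
    simulated character against the real factor labels; take the 95th
    nearest-rank percentile as the threshold. The result is significant iff
    the stratum passed the conventional screen AND the observed H strictly
    exceeds the threshold (ties are not significant). Both the add-one and
    the raw empirical p are reported.
    """
    if n_sims < 100:
        raise ValueError(
            f"n_sims must be >= 100 for a meaningful 95th percentile, got {n_sims}"
        )
    members = list(assignment.bins[assignment.bins == stratum_id].index)
    if not members:
        raise ValueError(f"stratum {stratum_id!r} has no species")
    missing = sorted(set(members) - set(tree.tip_labels))
    if missing:
        raise ValueError(f"stratum species missing from tree: {missing}")

    sub = table.set_index("species").loc[members]
    labels = sub["keap1_functional"].to_numpy()
    if len(np.unique(labels)) < 2:
        raise ValueError(f"stratum {stratum_id!r} lacks both factor levels")

    observed = kruskal_wallis(GroupedSample(sub[response].to_numpy(), labels))

    pruned = prune_to(tree, members)
    # align the trait matrix rows with the stratum table's species order
    cfg = BMConfig(
        sigma2=1.0, root_state=0.0, n_reps=n_sims,
        seed=stratum_seed(seed, stratum_id),
    )
    sim = simulate_bm(pruned, cfg)
    order = [sim.tip_labels.index(s) for s in members]
    null_h = kw_h_matrix(sim.values[order], labels)

    null = EmpiricalNull(null_h, n_sims, cfg.seed, stratum_id)
    threshold = empirical_percentile(null, 95.0)
    p_add_one, p_raw = empirical_p(null, observed.H)
    screened = observed.chisq_p < alpha
    n0 = int((labels == 0).sum())
    n1 = int((labels == 1).sum())
    return PIKWResult(
        stratum_id=stratum_id,
        n_per_level={"0": n0, "1": n1},
        observed_H=observed.H,
        chisq_p=observed.chisq_p,
        screened=screened,
        null=null,
        threshold_95=threshold,
        empirical_p_add_one=p_add_one,
        empirical_p_raw=p_raw,
        significant=bool(screened and observed.H > threshold),
    )


def run_pipeline(
    tree: TimeTree,
    table: pd.DataFrame,
    response: str,
    stratify_assignment: StratumAssignment,
    n_sims: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, PIKWResult]]:
    """Screen every stratum and run PI-KW on the testable ones.

    Returns a summary table (one row per occupied stratum) and the full
    per-stratum results for those with both factor levels present.
    Balance-check outcomes are logged and included in the summary.
    """
    screen = conventional_screen(table, stratify_assignment, response, alpha)
    balance = check_balance(stratify_assignment, table, alpha)
    results: dict[str, PIKWResult] = {}
    rows = []
    for stratum_id, (kw, screened) in screen.items():
        bal = balance.get(stratum_id)
        row = {
            "stratum": stratum_id,
            "variable": stratify_assignment.variable,
            "response": response,
            "n0": bal.n0 if bal else 0,
            "n1": bal.n1 if bal else 0,
            "balance_p": (
                bal.result.p_two_sided if bal and bal.testable else float("nan")
            ),
            "balance_pass": bal.passed if bal else None,
        }
        if kw is None:
            row.update(
                H=float("nan"), chisq_p=float("nan"), screened=False,
                threshold_95=float("nan"), empirical_p_add_one=float("nan"),
                empirical_p_raw=float("nan"), significant=False,
                tested=False,
            )
        else:
            res = run_pi_kw(
                tree, table, stratify_assignment, stratum_id, response,
                n_sims=n_sims, seed=seed, alpha=alpha,
            )
            results[stratum_id] = res
            row.update(
                H=res.observed_H, chisq_p=res.chisq_p, screened=res.screened,
                threshold_95=res.threshold_95,
                empirical_p_add_one=res.empirical_p_add_one,
                empirical_p_raw=res.empirical_p_raw,
                significant=res.significant, tested=True,
            )
        rows.append(row)
    summary = pd.DataFrame(rows)
    return summary, results


def write_results(
    summary: pd.DataFrame,
    results: dict[str, PIKWResult],
    out_dir: str | Path,
) -> None:
    """Write the summary TSV and one JSON per stratum (incl. null vector).

    Output is deterministic: fixed column order, sorted JSON keys, and
    repr-round-trip float formatting, so identical runs are byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cols = [
        "stratum", "variable", "response", "n0", "n1", "balance_p",
        "balance_pass", "H", "chisq_p", "screened", "threshold_95",
        "empirical_p_add_one", "empirical_p_raw", "significant", "tested",
    ]
    summary.to_csv(out_dir / "summary.tsv", sep="\t", index=False, columns=cols)
    for stratum_id, res in sorted(results.items()):
        record = asdict(res)
        record["null"] = {
            "h_values": [float(h) for h in res.null.h_values],
            "n_sims": res.null.n_sims,
            "seed": res.null.seed,
            "stratum_id": res.null.stratum_id,
        }
        safe = "".join(c if c.isalnum() else "_" for c in stratum_id)
        (out_dir / f"stratum_{safe}.json").write_text(
            json.dumps(record, sort_keys=True, indent=1) + "\n"
        )
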