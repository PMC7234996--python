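"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the statistical structure of the real study inputs,
none of which ship with the analysis: an ultrametric (time-calibrated)
phylogeny from a pure-birth process; a monophyletic clade labeled
KEAP1-nonfunctional (factor 0, the Neoaves analogue) covering a configurable
share of tips; continuous traits evolving by Brownian motion with an optional
clade-specific shift on the response trait; and promoter sequences with ARE
consensus instances planted at recorded positions.

Default conditions (see docs/methods.md): 80 tips, tree depth 1 (time is
expressed in units of total depth), BM rate sigma2 = 1, clade fraction 0.85
(mirroring the roughly 180/205 Neoaves share of the real cohort), traits
mapped through exp() so MS-BMR-like and lifespan-like columns are positive
and right-skewed. All downstream statistics are rank-based, so these scale
choices affect realism only, never test outcomes.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from .are_scan import ARE_CONSENSUS, IUPAC_SETS
from .bm_sim import BMConfig, simulate_bm
from .phylo import TimeTree, parse_newick, write_newick

__all__ = [
    "SynthConfig",
    "SynthTruth",
    "generate_tree",
    "label_clade",
    "generate_traits",
    "generate_promoters",
    "make_dataset",
    "write_dataset",
]


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic dataset."""

    n_tips: int = 80
    tree_depth: float = 1.0
    clade_fraction: float = 0.85  # share of tips labeled 0 (KEAP1-nonfunctional)
    sigma2_trait: float = 1.0
    clade_shift: float = 0.0  # added to the labeled clade's response latent
    trait_transform: str = "exponential"  # "identity" | "exponential"
    n_datasets: int = 1
    seed: int = 0
    # promoter fixtures
    n_promoters: int = 6
    promoter_length: int = 2000
    planted_counts: tuple = (0, 1, 2, 3, 2, 1)
    gc: float = 0.5

    def __post_init__(self):
        if self.n_tips < 4:
            raise ValueError("n_tips must be >= 4")
        if not 0 < self.clade_fraction < 1:
            raise ValueError("clade_fraction must be in (0, 1)")
        if not self.sigma2_trait > 0:
            raise ValueError("sigma2_trait must be > 0")
        if self.trait_transform not in ("identity", "exponential"):
            raise ValueError("trait_transform must be identity|exponential")


@dataclass
class SynthTruth:
    """Ground truth retained alongside generated data."""

    tree_newick: str
    labels: dict  # species -> 0/1
    clade_tips: list  # tips under the true clade node
    latent_response: dict  # species -> latent BM value incl. shift
    latent_lifespan: dict
    clade_shift: float
    planted_motifs: list = field(default_factory=list)  # dicts per plant


def generate_tree(n_tips: int, depth: float, seed: int) -> TimeTree:
    """Seeded pure-birth topology rescaled to an exactly ultrametric tree.

    Branch lengths are scaled so every tip sits at ``depth`` from the root;
    residual float error is absorbed into terminal edges, making the result
    ultrametric to machine precision by construction.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if not depth > 0:
        raise ValueError("depth must be > 0")
    if n_tips == 2:  # the pure-birth process stops at the first split
        from .phylo import Node

        root = Node(0.0, None, [Node(depth, "sp1"), Node(depth, "sp2")])
        return TimeTree(root)
    dtree = dendropy.model.birthdeath.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=random.Random(seed),
    )
    dtree.seed_node.edge.length = None  # no stem above the root
    tree = parse_newick(dtree.as_string(schema="newick"))

    depths = tree.tip_depths()
    scale = depth / max(depths.values())
    for node in tree.root.preorder():
        node.length *= scale
    # exact ultrametricity: put the rounding slack on the terminal edges
    depths = tree.tip_depths()
    for leaf in tree.root.leaves():
        leaf.length = max(0.0, leaf.length + depth - depths[leaf.label])
    # deterministic compact names in preorder leaf order
    width = len(str(n_tips))
    for i, leaf in enumerate(tree.root.leaves(), start=1):
        leaf.label = f"sp{i:0{width}d}"
    tree.validate()
    return tree


def label_clade(
    tree: TimeTree, clade_fraction: float, seed: int = 0
) -> tuple[dict, frozenset]:
    """Pick the clade whose size best matches ``clade_fraction`` of tips.

    Its descendants get factor 0 (KEAP1-nonfunctional), everything else 1.
    The selection is deterministic: among equally-sized candidates the clade
    with the lexicographically smallest descendant label wins (``seed`` is
    accepted for interface symmetry but never consulted). Both levels are
    guaranteed non-empty.
    """
    n = tree.n_tips
    target = clade_fraction * n
    best = None
    for node in tree.root.preorder():
        if node.is_leaf or node is tree.root:
            continue
        tips = sorted(leaf.label for leaf in node.leaves())
        if len(tips) >= n:  # would leave level 1 empty
            continue
        key = (abs(len(tips) - target), tips[0])
        if best is None or key < best[0]:
            best = (key, tips)
    if best is None:
        raise ValueError("no internal node yields two non-empty factor levels")
    clade = frozenset(best[1])
    labels = {t: (0 if t in clade else 1) for t in tree.tip_labels}
    return labels, clade


def _transform(latent: np.ndarray, transform: str, scale: float = 1.0):
    if transform == "identity":
        return latent * scale
    return np.exp(latent) * scale


def generate_traits(
    tree: TimeTree, labels: dict, cfg: SynthConfig
) -> tuple[pd.DataFrame, SynthTruth]:
    """Emit a full species trait table plus its ground truth.

    Two independent BM latents are drawn: a response latent (receiving
    ``clade_shift`` on the labeled clade, emitted as the MS-BMR-like trait)
    and a lifespan latent (no shift, emitted as the lifespan-like trait,
    scaled to a 20-year median). Body mass is a random power of two and
    BMR = ms_bmr * mass, so recomputing bmr/mass reproduces the stored
    ms_bmr column exactly in floating point.
    """
    species = tree.tip_labels
    lab = np.array([labels[s] for s in species])

    bm_resp = simulate_bm(
        tree, BMConfig(cfg.sigma2_trait, 0.0, 1, seed=cfg.seed * 2 + 0)
    )
    bm_life = simulate_bm(
        tree, BMConfig(cfg.sigma2_trait, 0.0, 1, seed=cfg.seed * 2 + 1)
    )
    order = [bm_resp.tip_labels.index(s) for s in species]
    latent_resp = bm_resp.values[order, 0] + cfg.clade_shift * (lab == 0)
    latent_life = bm_life.values[order, 0]

    ms_bmr = _transform(latent_resp, cfg.trait_transform)
    lifespan = _transform(latent_life, cfg.trait_transform, scale=20.0)

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    mass = 2.0 ** rng.integers(4, 14, size=len(species))
    quality = rng.choice(
        ["acceptable", "high", "questionable"], size=len(species),
        p=[0.6, 0.37, 0.03],
    )
    table = pd.DataFrame(
        {
            "species": species,
            "body_mass": mass,
            "bmr": ms_bmr * mass,
            "ms_bmr": ms_bmr,
            "max_lifespan": lifespan,
            "lifespan_quality": quality,
            "keap1_functional": lab,
        }
    )
    truth = SynthTruth(
        tree_newick=write_newick(tree),
        labels=dict(labels),
        clade_tips=sorted(s for s in species if labels[s] == 0),
        latent_response={s: float(v) for s, v in zip(species, latent_resp)},
        latent_lifespan={s: float(v) for s, v in zip(species, latent_life)},
        clade_shift=cfg.clade_shift,
    )
    return table, truth


def _random_expansion(rng: np.random.Generator, consensus: str) -> str:
    return "".join(
        IUPAC_SETS[ch][rng.integers(len(IUPAC_SETS[ch]))] for ch in consensus
    )


def generate_promoters(
    n_seqs: int,
    length: int,
    planted_counts: Sequence[int],
    gc: float,
    seed: int,
    window: int = 1000,
    consensus: str = ARE_CONSENSUS,
) -> tuple[list[tuple[str, str]], pd.DataFrame, list[dict]]:
    """Promoter FASTA records, BED loci, and planted-motif ground truth.

    Background bases are i.i.d. with the given GC fraction. For sequence i,
    ``planted_counts[i]`` non-overlapping instances drawn uniformly from the
    consensus expansions are written at random positions (random strand)
    inside the region an upstream scan of the paired BED locus will cover.
    """
    m = len(consensus)
    counts = list(planted_counts)
    if len(counts) != n_seqs:
        raise ValueError("planted_counts must have one entry per sequence")
    if length < 10 * max(counts, default=0) or length < window + m:
        raise ValueError("sequences too short to pack the requested plants")
    from Bio.Seq import Seq

    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    records, truth = [], []
    bed_rows = []
    plant_region = min(window, length) - m  # stay inside the scanned window
    for i, count in enumerate(counts):
        seq_id = f"promoter{i + 1:03d}"
        seq = rng.choice(list("ACGT"), size=length, p=probs)
        placed: list[int] = []
        attempts = 0
        while len(placed) < count:
            attempts += 1
            if attempts > 10000:
                raise ValueError("could not pack plants without overlap")
            pos = int(rng.integers(0, plant_region + 1))
            if all(abs(pos - p) >= m for p in placed):
                placed.append(pos)
        for pos in sorted(placed):
            instance = _random_expansion(rng, consensus)
            strand = "+" if rng.integers(2) == 0 else "-"
            written = (
                instance if strand == "+"
                else str(Seq(instance).reverse_complement())
            )
            seq[pos:pos + m] = list(written)
            truth.append(
                {"sequence_id": seq_id, "start": pos, "end": pos + m,
                 "strand": strand, "instance": instance}
            )
        records.append((seq_id, "".join(seq)))
        # gene locus placed just downstream of the scanned window
        bed_rows.append(
            {"chrom": seq_id, "start": window, "end": min(length, window + 100),
             "name": f"gene{i + 1:03d}", "score": "0", "strand": "+"}
        )
    return records, pd.DataFrame(bed_rows), truth


def make_dataset(cfg: SynthConfig) -> tuple[TimeTree, pd.DataFrame, SynthTruth]:
    """Tree + trait table + truth for one dataset under ``cfg``."""
    tree = generate_tree(cfg.n_tips, cfg.tree_depth, cfg.seed)
    labels, _ = label_clade(tree, cfg.clade_fraction)
    table, truth = generate_traits(tree, labels, cfg)
    return tree, table, truth


def write_dataset(
    cfg: SynthConfig, out_dir: str | Path, promoters: bool = True
) -> None:
    """Write tree.nwk, traits.tsv, promoters.fa, loci.bed and truth.json.

    Output is deterministic in cfg (byte-identical on re-run).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tree, table, truth = make_dataset(cfg)
    (out_dir / "tree.nwk").write_text(write_newick(tree) + "\n")
    table.to_csv(out_dir / "traits.tsv", sep="\t", index=False,
                 float_format="%.10g")
    if promoters:
        records, bed, planted = generate_promoters(
            cfg.n_promoters, cfg.promoter_length, cfg.planted_counts,
            cfg.gc, cfg.seed,
        )
        with open(out_dir / "promoters.fa", "w") as fh:
            for seq_id, seq in records:
                fh.write(f">{seq_id}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i:i + 70] + "\n")
        bed.to_csv(out_dir / "loci.bed", sep="\t", index=False, header=False)
        truth.planted_motifs = planted
    payload = asdict(truth)
    payload["config"] = asdict(cfg)
    (out_dir / "truth.json").write_text(
        json.dumps(payload, sort_keys=True, indent=1) + "\n"
    )
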