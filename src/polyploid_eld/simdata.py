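"""Synthetic three-library count data with known ground truth.

The generator emulates the statistical structure of an allopolyploid
expression study with one sequencing library per condition: maternal parent
(A), paternal parent (B) and the allopolyploid (C).  Each gene is assigned an
aggregate expression class and per-condition expected normalized means are
built from it:

============  =================================================
class         expected CPM means (b = per-gene base, e = 2^effect_log2fc)
============  =================================================
no_change     A = B = C = b
ELD_a_up      B = b;          A = C = b*e      (polyploid matches high mother)
ELD_a_down    B = b*e;        A = C = b        (polyploid matches low mother)
ELD_b_up      A = b;          B = C = b*e
ELD_b_down    A = b*e;        B = C = b
additive      {A, B} = {b, b*e} (fair coin);   C = (A + B)/2  (the MPV)
transgressive_up    A = B = b;    C = b*e
transgressive_down  A = B = b*e;  C = b  (equivalently C below both parents)
============  =================================================

Counts: the per-gene base mean is drawn log-uniformly over
``[base_mean/10, base_mean*10]`` to create a realistic dynamic range.  The
``dispersion`` parameter phi models gene-level expression heterogeneity as a
gamma latent factor with mean 1 and variance phi that is **shared across the
three libraries** of a gene; given the latent factor, each library's count is
Poisson with mean ``class_mean * latent * library_size / 1e6``.  Marginally
every count is negative binomial with variance ``m + phi*m**2``; because the
latent is shared, the counts of one gene across libraries are conditionally
Poisson, which is the sampling model the downstream exact test assumes.  A
single library per condition means between-individual biological variance is
not estimable in the emulated design, so the generator does not add it (see
the methods note for what this implies about real data).  ``dispersion=0``
degenerates to plain Poisson sampling.

miRNAs are generated with the same class machinery.  Predicted miRNA->target
pairs are planted such that a configurable fraction links a directionally
changed miRNA to a gene changed in the *opposite* direction in the same
polyploid-vs-parent comparison; the truth set of anti-correlated
(miRNA, gene, comparison) triples is derived from the planted means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .tables_io import ExpressionTable, ROLES

AGGREGATE_CLASSES = (
    "no_change",
    "additive",
    "ELD_a_up",
    "ELD_a_down",
    "ELD_b_up",
    "ELD_b_down",
    "transgressive_up",
    "transgressive_down",
)

#: default class mix: mostly unchanged genes, maternal (ELD-a) bias among the
#: dominance classes and a sizeable transgressive contingent, mirroring the
#: composition reported for the Raphanobrassica study.
DEFAULT_PROPORTIONS = {
    "no_change": 0.55,
    "additive": 0.10,
    "ELD_a_up": 0.06,
    "ELD_a_down": 0.03,
    "ELD_b_up": 0.045,
    "ELD_b_down": 0.035,
    "transgressive_up": 0.09,
    "transgressive_down": 0.09,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic experiment (all seed-controlled)."""

    n_genes: int = 10_000
    n_mirnas: int = 300
    class_proportions: dict = field(default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    effect_log2fc: float = 2.0
    base_mean: float = 200.0
    dispersion: float = 0.05
    library_sizes: tuple = (10_000_000, 10_000_000, 10_000_000)
    targets_per_mirna: int = 3
    anticorrelated_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_mirnas < 0:
            raise ConfigurationError("n_genes must be positive, n_mirnas non-negative")
        props = self.class_proportions
        unknown = set(props) - set(AGGREGATE_CLASSES)
        if unknown:
            raise ConfigurationError(f"unknown class names: {sorted(unknown)}")
        if any(v < 0 for v in props.values()):
            raise ConfigurationError("class proportions must be non-negative")
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ConfigurationError(
                f"class proportions must sum to 1, got {sum(props.values())}"
            )
        if self.effect_log2fc <= 0:
            raise ConfigurationError("effect_log2fc must be positive")
        if self.base_mean <= 0 or self.dispersion < 0:
            raise ConfigurationError("base_mean must be > 0 and dispersion >= 0")
        if len(self.library_sizes) != 3 or any(s <= 0 for s in self.library_sizes):
            raise ConfigurationError("library_sizes must be three positive integers")
        if self.targets_per_mirna < 0:
            raise ConfigurationError("targets_per_mirna must be >= 0")
        if not (0 <= self.anticorrelated_fraction <= 1):
            raise ConfigurationError("anticorrelated_fraction must be in [0, 1]")


@dataclass
class SyntheticExperiment:
    """Generated data plus every ground-truth label a test could need."""

    config: SimulationConfig
    gene_counts: ExpressionTable
    mirna_counts: ExpressionTable
    target_pairs: pd.DataFrame
    truth_gene_class: pd.Series
    truth_mirna_class: pd.Series
    truth_gene_means: pd.DataFrame   # expected CPM per library
    truth_mirna_means: pd.DataFrame
    truth_nonadditive: pd.Series
    truth_related_pairs: set  # {(mirna_id, gene_id, comparison)}

    def truth_direction(self, kind: str, comparison: str) -> pd.Series:
        """Planted DE direction (up/down/ns) from expected means.

        A feature is directionally changed in ``C-vs-A``/``C-vs-B`` when its
        planted mean ratio reaches two-fold; with the default effect sizes this
        reproduces the calls a thresholded DE test would make on noiseless data.
        """
        means = self.truth_gene_means if kind == "gene" else self.truth_mirna_means
        num, den = {"C-vs-A": ("C", "A"), "C-vs-B": ("C", "B"), "A-vs-B": ("A", "B")}[
            comparison
        ]
        ratio = np.log2(means[num] / means[den])
        out = np.where(ratio >= 1, "up", np.where(ratio <= -1, "down", "ns"))
        return pd.Series(out, index=means.index)

    def truth_calls(self, kind: str, comparison: str) -> pd.DataFrame:
        """DE-result-shaped frame with calls forced to the planted truth."""
        means = self.truth_gene_means if kind == "gene" else self.truth_mirna_means
        num, den = {"C-vs-A": ("C", "A"), "C-vs-B": ("C", "B"), "A-vs-B": ("A", "B")}[
            comparison
        ]
        call = self.truth_direction(kind, comparison)
        lfc = np.log2(means[num] / means[den])
        p = np.where(call == "ns", 1.0, 0.0)
        return pd.DataFrame(
            {"log2_ratio": lfc, "p": p, "q": p, "call": call}, index=means.index
        )


def _class_means(classes: np.ndarray, base: np.ndarray, effect: float,
                 coin: np.ndarray) -> pd.DataFrame:
    """Expected CPM per library from class labels (vectorized)."""
    e = 2.0 ** effect
    a = base.copy()
    b = base.copy()
    c = base.copy()
    m = classes == "ELD_a_up"
    a[m] = c[m] = base[m] * e
    m = classes == "ELD_a_down"
    b[m] = base[m] * e
    m = classes == "ELD_b_up"
    b[m] = c[m] = base[m] * e
    m = classes == "ELD_b_down"
    a[m] = base[m] * e
    m = classes == "additive"
    hi = m & coin          # A is the high parent
    lo = m & ~coin
    a[hi] = base[hi] * e
    b[lo] = base[lo] * e
    c[m] = (a[m] + b[m]) / 2.0
    m = classes == "transgressive_up"
    c[m] = base[m] * e
    m = classes == "transgressive_down"
    a[m] = b[m] = base[m] * e
    return pd.DataFrame({"A": a, "B": b, "C": c})


def _draw_counts(means: pd.DataFrame, cfg: SimulationConfig,
                 rng: np.random.Generator) -> pd.DataFrame:
    """Shared-gamma-latent Poisson sampling; marginally NB(m, phi)."""
    n = len(means)
    if cfg.dispersion > 0:
        shape = 1.0 / cfg.dispersion
        latent = rng.gamma(shape, cfg.dispersion, size=n)
    else:
        latent = np.ones(n)
    out = {}
    for role, size in zip(ROLES, cfg.library_sizes):
        lam = means[role].to_numpy() * latent * (size / 1e6)
        out[role] = rng.poisson(lam)
    return pd.DataFrame(out, index=means.index).astype(np.int64)


def simulate_counts(config: SimulationConfig) -> SyntheticExperiment:
    """Generate a full synthetic experiment; deterministic for a fixed config."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    names = sorted(cfg.class_proportions)
    probs = np.array([cfg.class_proportions[k] for k in names])

    gene_ids = pd.Index([f"gene{i:05d}" for i in range(cfg.n_genes)], name="feature_id")
    gene_cls = np.array(names)[rng.choice(len(names), size=cfg.n_genes, p=probs)]
    gene_base = np.exp(
        rng.uniform(np.log(cfg.base_mean / 10), np.log(cfg.base_mean * 10), cfg.n_genes)
    )
    gene_coin = rng.random(cfg.n_genes) < 0.5
    gene_means = _class_means(gene_cls, gene_base, cfg.effect_log2fc, gene_coin)
    gene_means.index = gene_ids
    gene_counts = ExpressionTable(
        _draw_counts(gene_means, cfg, rng),
        library_sizes=pd.Series(dict(zip(ROLES, cfg.library_sizes))),
    )

    mirna_ids = pd.Index(
        [f"mir{i:04d}" for i in range(cfg.n_mirnas)], name="feature_id"
    )
    mirna_cls = np.array(names)[rng.choice(len(names), size=cfg.n_mirnas, p=probs)]
    mirna_base = np.exp(
        rng.uniform(np.log(cfg.base_mean / 10), np.log(cfg.base_mean * 10), cfg.n_mirnas)
    )
    mirna_coin = rng.random(cfg.n_mirnas) < 0.5
    mirna_means = _class_means(mirna_cls, mirna_base, cfg.effect_log2fc, mirna_coin)
    mirna_means.index = mirna_ids
    mirna_counts = ExpressionTable(
        _draw_counts(mirna_means, cfg, rng),
        library_sizes=pd.Series(dict(zip(ROLES, cfg.library_sizes))),
    )

    # non-additivity truth: planted C deviates >= 2-fold from the planted MPV
    mpv = (gene_means["A"] + gene_means["B"]) / 2.0
    truth_nonadd = (np.abs(np.log2(gene_means["C"] / mpv)) >= 1.0)

    exp = SyntheticExperiment(
        config=cfg,
        gene_counts=gene_counts,
        mirna_counts=mirna_counts,
        target_pairs=pd.DataFrame(columns=["mirna_id", "gene_id"]),
        truth_gene_class=pd.Series(gene_cls, index=gene_ids),
        truth_mirna_class=pd.Series(mirna_cls, index=mirna_ids),
        truth_gene_means=gene_means,
        truth_mirna_means=mirna_means,
        truth_nonadditive=truth_nonadd,
        truth_related_pairs=set(),
    )

    # --- plant predicted target pairs -------------------------------------
    pair_rows: list[tuple[str, str]] = []
    gene_dir = {
        c: exp.truth_direction("gene", c).to_numpy() for c in ("C-vs-A", "C-vs-B")
    }
    mirna_dir = {
        c: exp.truth_direction("mirna", c) for c in ("C-vs-A", "C-vs-B")
    }
    opposite = {"up": "down", "down": "up"}
    gene_pool = {
        (c, d): gene_ids[gene_dir[c] == d]
        for c in ("C-vs-A", "C-vs-B")
        for d in ("up", "down")
    }
    for mid in mirna_ids:
        # comparisons where this miRNA has a planted direction
        directional = [
            (c, mirna_dir[c].loc[mid])
            for c in ("C-vs-A", "C-vs-B")
            if mirna_dir[c].loc[mid] != "ns"
        ]
        chosen: set[str] = set()
        for _ in range(cfg.targets_per_mirna):
            anti = directional and rng.random() < cfg.anticorrelated_fraction
            if anti:
                comp, mdir = directional[int(rng.integers(len(directional)))]
                pool = gene_pool[(comp, opposite[mdir])]
            else:
                pool = gene_ids
            pool = pool.difference(chosen)
            if len(pool) == 0:
                continue
            gid = pool[int(rng.integers(len(pool)))]
            chosen.add(gid)
            pair_rows.append((mid, gid))
    pairs = pd.DataFrame(pair_rows, columns=["mirna_id", "gene_id"]).drop_duplicates(
        ignore_index=True
    )
    exp.target_pairs = pairs

    # truth anti-correlated triples derive from planted means, covering pairs
    # that landed opposite by chance as well as the intentionally planted ones
    related: set[tuple[str, str, str]] = set()
    gdir_s = {c: exp.truth_direction("gene", c) for c in ("C-vs-A", "C-vs-B")}
    for comp in ("C-vs-A", "C-vs-B"):
        md = mirna_dir[comp]
        gd = gdir_s[comp]
        for mid, gid in pairs.itertuples(index=False):
            m, g = md.loc[mid], gd.loc[gid]
            if m != "ns" and g != "ns" and m != g:
                related.add((mid, gid, comp))
    exp.truth_related_pairs = related
    return exp


def write_experiment(exp: SyntheticExperiment, outdir) -> dict:
    """Write counts, pairs and truth tables as TSV; returns the path map."""
    import os

    from . import tables_io

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "gene_counts": os.path.join(outdir, "gene_counts.tsv"),
        "mirna_counts": os.path.join(outdir, "mirna_counts.tsv"),
        "library_sizes": os.path.join(outdir, "library_sizes.tsv"),
        "target_pairs": os.path.join(outdir, "target_pairs.tsv"),
        "truth_genes": os.path.join(outdir, "truth_genes.tsv"),
        "truth_mirnas": os.path.join(outdir, "truth_mirnas.tsv"),
        "truth_related_pairs": os.path.join(outdir, "truth_related_pairs.tsv"),
    }
    tables_io.write_counts(exp.gene_counts, paths["gene_counts"])
    tables_io.write_counts(exp.mirna_counts, paths["mirna_counts"])
    tables_io.write_library_sizes(exp.gene_counts.library_sizes, paths["library_sizes"])
    tables_io.write_target_pairs(exp.target_pairs, paths["target_pairs"])
    truth_g = pd.DataFrame(
        {
            "class": exp.truth_gene_class,
            "nonadditive": exp.truth_nonadditive.astype(int),
        }
    )
    truth_g.index.name = "feature_id"
    truth_g.to_csv(paths["truth_genes"], sep="\t")
    truth_m = pd.DataFrame({"class": exp.truth_mirna_class})
    truth_m.index.name = "feature_id"
    truth_m.to_csv(paths["truth_mirnas"], sep="\t")
    pd.DataFrame(
        sorted(exp.truth_related_pairs), columns=["mirna_id", "gene_id", "comparison"]
    ).to_csv(paths["truth_related_pairs"], sep="\t", index=False)
    return paths
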