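"""Synthetic data generators mirroring the statistical structure the
analysis assumes: branching NB trajectory counts with known peak times,
Poisson counts from a known regulatory network with known per-cell TF
activities, and paired pre/post-injury expression plus accessibility
fragments with known priming classes.

Every generator takes an explicit seed and is bit-reproducible.  Ground
truth is emitted alongside the data so each downstream stage can be scored
against what was simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nbgam import TrajectoryDataset

__all__ = [
    "GeneProgram",
    "TrajectoryTruth",
    "GRNTruth",
    "PrimingTruth",
    "PrimingSim",
    "make_programs",
    "simulate_trajectory_counts",
    "simulate_grn_dataset",
    "simulate_priming_dataset",
    "truth_report",
]

#: Smallest log-scale bump height treated as detectable.  Below this the
#: expected derivative of the log-mean stays under the cascade test's
#: threshold c = 0.1 for the bump widths generated here.
DETECTABILITY_FLOOR = 0.5

#: log-normal sigma for per-cell depth offsets N_i.
OFFSET_SIGMA = 0.3


@dataclass
class GeneProgram:
    """Generating program of one gene: a Gaussian bump on the log scale.

    The per-lineage log-mean at pseudotime t is
    ``baseline + amplitude * exp(-(t - peak_time)^2 / (2 width^2))``,
    which has a unique interior maximum at ``peak_time`` and a one-signed
    derivative before it.  ``amplitude = 0`` in every lineage marks a null
    (flat) gene.
    """

    gene_id: str
    baseline: np.ndarray       # (L,) natural-log counts
    amplitude: np.ndarray      # (L,) log-scale bump height, >= 0
    peak_time: np.ndarray      # (L,) pseudotime units
    width: np.ndarray          # (L,) pseudotime units, > 0
    dispersion: float          # NB size phi_g, > 0

    def __post_init__(self) -> None:
        for name in ("baseline", "amplitude", "peak_time", "width"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float)))
        if np.any(self.width <= 0):
            raise ValueError("width must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if np.any(self.amplitude < 0):
            raise ValueError("amplitude must be nonnegative")

    @property
    def n_lineages(self) -> int:
        return self.baseline.size

    def log_mean(self, t: np.ndarray, lineage: int) -> np.ndarray:
        b = self.baseline[lineage]
        a = self.amplitude[lineage]
        p = self.peak_time[lineage]
        w = self.width[lineage]
        return b + a * np.exp(-((t - p) ** 2) / (2.0 * w * w))


@dataclass
class TrajectoryTruth:
    """Per (gene, lineage) generating truth for trajectory simulations."""

    table: pd.DataFrame  # gene, lineage, involved, true_peak, amplitude, specific_lineage, shared


@dataclass
class GRNTruth:
    """Generating truth of a regulatory-network count simulation."""

    edges: pd.DataFrame          # tf, target, beta
    activity: pd.DataFrame       # TF x cell true activities a_ti
    offsets: np.ndarray          # (n_cells,) N_i
    pseudotime: np.ndarray       # (n_cells,) ordering coordinate


@dataclass
class PrimingTruth:
    """Per-gene generating truth of the priming simulation."""

    table: pd.DataFrame  # gene, class, expr_pre, expr_post, acc_pre_cpm, acc_post_cpm
    accessibility_floor_cpm: float


@dataclass
class PrimingSim:
    """All artifacts of one priming simulation."""

    expression: pd.DataFrame     # gene, expr_pre, expr_post
    de: pd.DataFrame             # gene, lfc, fdr
    fragments_pre: pd.DataFrame  # BED-style: chrom, start, end (0-based half-open)
    fragments_post: pd.DataFrame
    tss: pd.DataFrame            # gene, chrom, tss (1-based), strand
    truth: PrimingTruth


def make_programs(
    n_genes: int,
    n_lineages: int = 3,
    frac_null: float = 0.0,
    seed: int = 0,
    pseudotime_range: tuple[float, float] = (0.0, 10.0),
    baseline_range: tuple[float, float] = (0.5, 1.5),
    amplitude_range: tuple[float, float] = (1.5, 2.5),
    peak_range: tuple[float, float] = (1.0, 9.0),
    width_range: tuple[float, float] = (1.2, 1.8),
    dispersion: float = 2.0,
) -> list[GeneProgram]:
    """Draw random gene programs: bump genes plus a fraction of null genes.

    Defaults encode a moderately expressed transcription factor whose
    induction spans roughly a third of the trajectory: baseline 1.6-4.5
    counts per unit depth, a 4.5-12-fold peak induction, bump width
    1.2-1.8 pseudotime units on a [0, 10] trajectory, NB size 2.
    """
    rng = np.random.default_rng(seed)
    n_null = int(round(frac_null * n_genes))
    programs = []
    for i in range(n_genes):
        null = i < n_null
        programs.append(
            GeneProgram(
                gene_id=f"g{i:04d}",
                baseline=rng.uniform(*baseline_range, n_lineages),
                amplitude=(np.zeros(n_lineages) if null
                           else rng.uniform(*amplitude_range, n_lineages)),
                peak_time=rng.uniform(*peak_range, n_lineages),
                width=rng.uniform(*width_range, n_lineages),
                dispersion=dispersion,
            )
        )
    return programs


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    p = phi / (phi + mean)
    return rng.negative_binomial(phi, p)


def simulate_trajectory_counts(
    programs: list[GeneProgram],
    cells_per_lineage: int,
    pseudotime_range: tuple[float, float] = (0.0, 10.0),
    seed: int = 0,
) -> tuple[TrajectoryDataset, TrajectoryTruth]:
    """Sample NB counts along a branching trajectory with known programs.

    Pseudotimes are uniform per lineage over a shared range (the lineages
    share a trajectory origin), offsets are log-normal around 1, and each
    cell is hard-assigned to the lineage it was sampled on.
    """
    if not programs:
        raise ValueError("need at least one gene program")
    if cells_per_lineage < 2:
        raise ValueError("need at least 2 cells per lineage")
    L = programs[0].n_lineages
    if any(p.n_lineages != L for p in programs):
        raise ValueError("all programs must share the lineage count")
    rng = np.random.default_rng(seed)
    lo, hi = pseudotime_range
    n_cells = cells_per_lineage * L

    t = rng.uniform(lo, hi, n_cells)
    lineage = np.repeat(np.arange(L), cells_per_lineage)
    offsets = np.exp(rng.normal(0.0, OFFSET_SIGMA, n_cells))
    T = np.zeros((n_cells, L))
    T[np.arange(n_cells), lineage] = t

    counts = np.zeros((len(programs), n_cells), dtype=np.int64)
    rows = []
    for gi, prog in enumerate(programs):
        for l in range(L):
            mask = lineage == l
            mu = offsets[mask] * np.exp(prog.log_mean(t[mask], l))
            counts[gi, mask] = _nb_sample(rng, mu, prog.dispersion)
            amp = prog.amplitude[l]
            rows.append(
                {
                    "gene": prog.gene_id,
                    "lineage": l,
                    "involved": bool(amp >= DETECTABILITY_FLOOR),
                    "true_peak": float(np.clip(prog.peak_time[l], lo, hi)) if amp > 0 else np.nan,
                    "amplitude": float(amp),
                }
            )
    data = TrajectoryDataset(
        counts=counts,
        genes=[p.gene_id for p in programs],
        cells=[f"c{i:05d}" for i in range(n_cells)],
        pseudotime=T,
        lineage=lineage,
        offsets=offsets,
        covariates=np.zeros((n_cells, 0)),
    )
    return data, TrajectoryTruth(pd.DataFrame(rows))


def simulate_grn_dataset(
    n_tfs: int = 10,
    n_targets: int = 100,
    n_cells: int = 500,
    median_out_degree: int = 27,
    seed: int = 0,
    pseudotime_range: tuple[float, float] = (0.0, 10.0),
) -> tuple[pd.DataFrame, GRNTruth]:
    """Poisson counts from a known TF -> target network.

    Each TF regulates a random target set whose size is calibrated so the
    median out-degree matches ``median_out_degree`` (default 27, a typical
    value for single-cell regulons).  Per-cell activities are smooth
    nonnegative bumps over a pseudotime ordering; counts are
    ``Y_gi ~ Poisson(N_i * sum_t beta_tg a_ti)``.
    """
    rng = np.random.default_rng(seed)
    tfs = [f"tf{t:03d}" for t in range(n_tfs)]
    targets = [f"tg{g:04d}" for g in range(n_targets)]

    # out-degrees log-normal around the requested median; the degree budget
    # must cover every target with at least one parent
    out_deg = np.maximum(
        1, np.round(median_out_degree * np.exp(rng.normal(0.0, 0.35, n_tfs)))
    ).astype(int)
    out_deg = np.minimum(out_deg, n_targets)
    if out_deg.sum() < n_targets:
        raise ValueError(
            "degree budget cannot give every target a parent; "
            "raise median_out_degree or n_tfs, or lower n_targets"
        )
    # one edge per degree slot: the first n_targets shuffled slots pin a
    # parent on each target, the rest attach to random targets
    slots = np.repeat(np.arange(n_tfs), out_deg)
    rng.shuffle(slots)
    perm = rng.permutation(n_targets)
    edges: dict[tuple[int, int], float] = {}
    for j, ti in enumerate(slots):
        gi = perm[j] if j < n_targets else int(rng.integers(n_targets))
        edges.setdefault((int(ti), int(gi)), float(rng.gamma(2.0, 0.5)))

    lo, hi = pseudotime_range
    s = np.sort(rng.uniform(lo, hi, n_cells))
    peaks = rng.uniform(lo, hi, n_tfs)
    widths = rng.uniform(1.0, 2.5, n_tfs)
    base = rng.uniform(0.1, 0.3, n_tfs)
    amp = rng.uniform(1.0, 3.0, n_tfs)
    activity = base[:, None] + amp[:, None] * np.exp(
        -((s[None, :] - peaks[:, None]) ** 2) / (2.0 * widths[:, None] ** 2)
    )
    offsets = np.exp(rng.normal(0.0, OFFSET_SIGMA, n_cells))

    beta = np.zeros((n_tfs, n_targets))
    for (ti, gi), w in edges.items():
        beta[ti, gi] = w
    lam = offsets[None, :] * (beta.T @ activity)
    counts = rng.poisson(lam)

    cells = [f"c{i:05d}" for i in range(n_cells)]
    counts_df = pd.DataFrame(counts, index=targets, columns=cells)
    edges_df = pd.DataFrame(
        [(tfs[t], targets[g], w) for (t, g), w in sorted(edges.items())],
        columns=["tf", "target", "beta"],
    )
    truth = GRNTruth(
        edges=edges_df,
        activity=pd.DataFrame(activity, index=tfs, columns=cells),
        offsets=offsets,
        pseudotime=s,
    )
    return counts_df, truth


def simulate_priming_dataset(
    n_per_class: dict[str, int] | int = 25,
    seed: int = 0,
    accessibility_floor_cpm: float = 500.0,
    library_size: int = 20_000,
    fragment_length: int = 100,
    flank: int = 2_000,
) -> PrimingSim:
    """Paired pre/post-injury bulk expression and ATAC fragments with known
    priming classes.

    Classes are generated strictly outside the +-0.5 accessibility
    log2-fold-change window and well away from the accessibility floor, so
    the generated labels are unambiguous under the downstream classifier:

    - ``primed``: silent pre-expression, induced post, open chromatin whose
      accessibility barely changes (|log2FC| <= 0.2).
    - ``induced_accessible``: silent pre, induced post, near-zero pre
      accessibility that opens after injury (log2FC >= 1.5).
    - ``constitutive``: expressed before injury, open and stable chromatin.
    - ``silent_closed``: silent and closed throughout.

    Both fragment libraries are padded with filler fragments on a decoy
    contig to exactly ``library_size`` records, so CPM ratios equal count
    ratios.
    """
    classes = ["primed", "induced_accessible", "constitutive", "silent_closed"]
    if isinstance(n_per_class, int):
        if n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        n_per_class = {c: n_per_class for c in classes}
    unknown = set(n_per_class) - set(classes)
    if unknown:
        raise ValueError(f"unknown priming classes: {sorted(unknown)}")
    rng = np.random.default_rng(seed)

    cpm_per_count = 1e6 / library_size
    floor_counts = accessibility_floor_cpm / cpm_per_count  # 10 counts by default

    rows = []
    idx = 0
    for cls in classes:
        for _ in range(n_per_class.get(cls, 0)):
            gene = f"pg{idx:04d}"
            tss = 5_000 + 10_000 * idx  # 1-based, one gene per 10 kb
            strand = "+" if idx % 2 == 0 else "-"
            if cls == "primed":
                expr_pre = rng.uniform(0.01, 0.3)
                expr_post = rng.uniform(10, 60)
                lfc = np.log2((expr_post + 0.1) / (expr_pre + 0.1))
                fdr = rng.uniform(1e-8, 1e-4)
                acc_pre = int(round(floor_counts * rng.uniform(15, 25)))
                acc_post = int(round(acc_pre * 2 ** rng.uniform(-0.2, 0.2)))
            elif cls == "induced_accessible":
                expr_pre = rng.uniform(0.01, 0.3)
                expr_post = rng.uniform(10, 60)
                lfc = np.log2((expr_post + 0.1) / (expr_pre + 0.1))
                fdr = rng.uniform(1e-8, 1e-4)
                acc_pre = int(rng.integers(0, max(2, int(floor_counts * 0.3))))
                acc_post = int(round(floor_counts * rng.uniform(15, 25)))
            elif cls == "constitutive":
                expr_pre = rng.uniform(30, 200)
                expr_post = expr_pre * 2 ** rng.uniform(-0.3, 0.3)
                lfc = np.log2((expr_post + 0.1) / (expr_pre + 0.1))
                fdr = rng.uniform(0.2, 1.0)
                acc_pre = int(round(floor_counts * rng.uniform(15, 25)))
                acc_post = int(round(acc_pre * 2 ** rng.uniform(-0.2, 0.2)))
            else:  # silent_closed
                expr_pre = rng.uniform(0.0, 0.05)
                expr_post = rng.uniform(0.0, 0.05)
                lfc = np.log2((expr_post + 0.1) / (expr_pre + 0.1))
                fdr = rng.uniform(0.5, 1.0)
                acc_pre = int(rng.integers(0, 3))
                acc_post = int(rng.integers(0, 3))
            rows.append(
                {
                    "gene": gene, "class": cls, "tss": tss, "strand": strand,
                    "expr_pre": expr_pre, "expr_post": expr_post,
                    "lfc": lfc, "fdr": fdr,
                    "acc_pre_count": acc_pre, "acc_post_count": acc_post,
                }
            )
            idx += 1
    genes = pd.DataFrame(rows)

    def _fragments(count_col: str) -> pd.DataFrame:
        recs = []
        for _, g in genes.iterrows():
            n = int(g[count_col])
            if n == 0:
                continue
            tss0 = g["tss"] - 1
            lo = max(0, tss0 - flank)
            starts = rng.integers(lo, tss0 + flank - 1, n)
            for st in np.sort(starts):
                recs.append(("chr1", int(st), int(st) + fragment_length))
        n_fill = library_size - len(recs)
        if n_fill < 0:
            raise ValueError("library_size too small for the generated per-gene counts")
        fill_starts = np.sort(rng.integers(0, 50_000_000, n_fill))
        recs.extend(("chrFiller", int(st), int(st) + fragment_length) for st in fill_starts)
        return pd.DataFrame(recs, columns=["chrom", "start", "end"])

    fragments_pre = _fragments("acc_pre_count")
    fragments_post = _fragments("acc_post_count")

    truth_table = genes[["gene", "class", "expr_pre", "expr_post"]].copy()
    truth_table["acc_pre_cpm"] = genes["acc_pre_count"] * cpm_per_count
    truth_table["acc_post_cpm"] = genes["acc_post_count"] * cpm_per_count
    return PrimingSim(
        expression=genes[["gene", "expr_pre", "expr_post"]].copy(),
        de=genes[["gene", "lfc", "fdr"]].copy(),
        fragments_pre=fragments_pre,
        fragments_post=fragments_post,
        tss=genes[["gene"]].assign(chrom="chr1", tss=genes["tss"], strand=genes["strand"]),
        truth=PrimingTruth(truth_table, accessibility_floor_cpm),
    )


def truth_report(truth) -> pd.DataFrame:
    """Flatten any truth object to a single table that round-trips via TSV."""
    if isinstance(truth, TrajectoryTruth):
        return truth.table.copy()
    if isinstance(truth, GRNTruth):
        return truth.edges.copy()
    if isinstance(truth, PrimingTruth):
        return truth.table.copy()
    raise TypeError(f"unknown truth type: {type(truth).__name__}")
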