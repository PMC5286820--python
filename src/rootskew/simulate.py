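"""Seeded generators with planted ground truth.

Two generators make the whole pipeline testable end to end with no
external data:

* :func:`simulate_traces` draws root polylines per (ecotype x plate-angle)
  cell — a straight growth axis tilted by a planted skew angle from
  vertical, a sinusoidal lateral component with a planted number of full
  waves, and Gaussian positional jitter — together with a truth table of
  the planted parameters and the metric values a perfect measurement
  would recover.

* :func:`simulate_expression` draws a log2 expression matrix for the
  2-ecotype x 3-angle x n-replicate design in which each gene belongs to
  a planted effect class: NULL (no effect), INHERENT (constant
  Col-0-vs-WS offset at every angle, which the inherent filter should
  remove), CAT_I..CAT_VI (each of the six between-ecotype significance
  patterns), WS_ANGLE_45 / WS_ANGLE_135 (WS responds to the tilted angle
  relative to its vertical control), and HPSGC_LIKE (a WS-specific
  response at 135 degrees, which lands the gene in the within-WS 135 DE
  set and in Category VI and therefore in the HPSGC set).  Shifting WS
  alone at a tilted angle already creates the between-ecotype difference
  at that angle, so WS_ANGLE_135 and HPSGC_LIKE genes share identical
  expectations; both are listed separately so truth tables stay explicit
  about intent.

* :func:`study_scale_comparison_matrix` builds a deterministic,
  noise-free synthetic comparison matrix directly at the contrast level,
  planting set-level structure (category sizes and directions, within-WS
  set sizes and overlaps, overlap-set composition) so the set-algebra and
  classification stages can be checked against exact expected counts.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffexpr import (
    BETWEEN_ANGLES,
    ContrastResult,
    ExpressionStudy,
    bh_fdr,
    between_contrast_id,
    within_contrast_id,
)
from .morphometrics import ANGLES, ECOTYPES, RootTrace
from .patterns import ComparisonMatrix

# ---------------------------------------------------------------------------
# root traces
# ---------------------------------------------------------------------------

# Default planted phenotypes per (ecotype, angle): WS skews strongly on
# tilted plates and waves at 45 degrees with reduced waving at 135; Col-0
# waves at 45 but barely skews; vertical plates do neither.
DEFAULT_SKEW_DEG = {
    ("Col-0", 45): 2.0,
    ("Col-0", 90): 0.0,
    ("Col-0", 135): 2.0,
    ("WS", 45): 20.0,
    ("WS", 90): 0.0,
    ("WS", 135): 20.0,
}
DEFAULT_WAVES = {
    ("Col-0", 45): 4,
    ("Col-0", 90): 0,
    ("Col-0", 135): 0,
    ("WS", 45): 4,
    ("WS", 90): 0,
    ("WS", 135): 1,
}


@dataclass(frozen=True)
class TraceSimConfig:
    """Planted per-cell phenotypes for the trace generator."""

    seed: int
    n_roots: int = 12
    length_mm: float = 25.0
    n_points: int = 300
    skew_angle_deg: dict = field(default_factory=lambda: dict(DEFAULT_SKEW_DEG))
    wave_count: dict = field(default_factory=lambda: dict(DEFAULT_WAVES))
    wave_amplitude_mm: float = 0.5
    noise_sd_mm: float = 0.05

    def __post_init__(self) -> None:
        if self.n_roots < 1 or self.n_points < 2:
            raise ValueError("n_roots >= 1 and n_points >= 2 required")
        if self.length_mm <= 0 or self.wave_amplitude_mm < 0 or self.noise_sd_mm < 0:
            raise ValueError("lengths, amplitudes and noise must be non-negative")


def _root_curve(
    length: float,
    skew_deg: float,
    waves: int,
    amplitude: float,
    n_points: int,
) -> np.ndarray:
    """Noiseless planted curve: tilted axis plus a sinusoidal lateral term."""
    theta = np.deg2rad(skew_deg)
    t = np.linspace(0.0, length, n_points)
    axis = np.array([np.sin(theta), np.cos(theta)])  # y downward
    perp = np.array([np.cos(theta), -np.sin(theta)])
    lateral = amplitude * np.sin(2.0 * np.pi * waves * t / length)
    return t[:, None] * axis[None, :] + lateral[:, None] * perp[None, :]


def _smooth_noise(
    rng: np.random.Generator, n_points: int, sd: float, knot_every: int = 15
) -> np.ndarray:
    """Correlated positional jitter: Gaussian displacements at coarse knots,
    linearly interpolated along the trace.  Tracing error is smooth along a
    root; independent per-point jitter would spuriously inflate arc length.
    """
    if sd == 0.0:
        return np.zeros((n_points, 2))
    n_knots = max(4, n_points // knot_every)
    knots = np.linspace(0, n_points - 1, n_knots)
    vals = rng.normal(0.0, sd, size=(n_knots, 2))
    idx = np.arange(n_points)
    return np.column_stack(
        [np.interp(idx, knots, vals[:, 0]), np.interp(idx, knots, vals[:, 1])]
    )


def simulate_traces(
    cfg: TraceSimConfig,
) -> tuple[list[RootTrace], pd.DataFrame]:
    """Draw all roots; returns (traces, truth table).

    The truth table records per root the planted skew angle and wave
    count, the expected HGI (= sin(skew) for the noiseless path, which has
    an integer number of wave periods and hence no net lateral tip
    displacement), the expected straightness (chord over arc of the
    noiseless curve) and the expected wave density (planted count over the
    densely integrated noiseless arc length).
    """
    rng = np.random.default_rng(cfg.seed)
    traces: list[RootTrace] = []
    truth_rows = []
    for eco in ECOTYPES:
        for angle in ANGLES:
            skew = float(cfg.skew_angle_deg.get((eco, angle), 0.0))
            waves = int(cfg.wave_count.get((eco, angle), 0))
            amp = cfg.wave_amplitude_mm if waves > 0 else 0.0
            # dense noiseless reference for the planted arc length
            ref = _root_curve(cfg.length_mm, skew, waves, amp, 20 * cfg.n_points)
            seg = np.diff(ref, axis=0)
            arc_true = float(np.hypot(seg[:, 0], seg[:, 1]).sum())
            chord_true = float(np.hypot(*(ref[-1] - ref[0])))
            for rep in range(1, cfg.n_roots + 1):
                pts = _root_curve(
                    cfg.length_mm, skew, waves, amp, cfg.n_points
                ) + _smooth_noise(rng, cfg.n_points, cfg.noise_sd_mm)
                trace_id = f"{eco.replace('-', '')}_{angle}_{rep:03d}"
                traces.append(
                    RootTrace(
                        trace_id=trace_id,
                        ecotype=eco,
                        angle_gp=angle,
                        replicate=rep,
                        points=pts,
                    )
                )
                truth_rows.append(
                    {
                        "trace_id": trace_id,
                        "ecotype": eco,
                        "angle_gp": angle,
                        "skew_angle_deg": skew,
                        "wave_count": waves,
                        "expected_hgi": float(np.sin(np.deg2rad(skew))),
                        "expected_str": chord_true / arc_true,
                        "expected_wd": waves / arc_true,
                    }
                )
    return traces, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------

EXPR_CLASSES = (
    "NULL",
    "INHERENT",
    "CAT_I",
    "CAT_II",
    "CAT_III",
    "CAT_IV",
    "CAT_V",
    "CAT_VI",
    "WS_ANGLE_45",
    "WS_ANGLE_135",
    "HPSGC_LIKE",
)

DEFAULT_CLASS_COUNTS = {
    "NULL": 1700,
    "INHERENT": 60,
    "CAT_I": 25,
    "CAT_II": 25,
    "CAT_III": 25,
    "CAT_IV": 25,
    "CAT_V": 25,
    "CAT_VI": 25,
    "WS_ANGLE_45": 30,
    "WS_ANGLE_135": 30,
    "HPSGC_LIKE": 30,
}

# cells shifted by +effect, per class
_CLASS_SHIFTS: dict[str, tuple[tuple[str, int], ...]] = {
    "NULL": (),
    "INHERENT": (("Col-0", 45), ("Col-0", 90), ("Col-0", 135)),
    "CAT_I": (("Col-0", 90),),
    "CAT_II": (("Col-0", 90), ("Col-0", 45)),
    "CAT_III": (("Col-0", 90), ("Col-0", 135)),
    "CAT_IV": (("Col-0", 45),),
    "CAT_V": (("Col-0", 45), ("Col-0", 135)),
    "CAT_VI": (("Col-0", 135),),
    "WS_ANGLE_45": (("WS", 45),),
    "WS_ANGLE_135": (("WS", 135),),
    "HPSGC_LIKE": (("WS", 135),),
}

# expected pipeline outcome per class:
# (category, in_ws45, in_ws135, hpsgc, removed)
_CLASS_EXPECTATIONS = {
    "NULL": ("NONE", False, False, False, False),
    "INHERENT": ("REMOVED_INHERENT", False, False, False, True),
    "CAT_I": ("I", False, False, False, False),
    "CAT_II": ("II", False, False, False, False),
    "CAT_III": ("III", False, False, False, False),
    "CAT_IV": ("IV", False, False, False, False),
    "CAT_V": ("V", False, False, False, False),
    "CAT_VI": ("VI", False, False, False, False),
    "WS_ANGLE_45": ("IV", True, False, False, False),
    "WS_ANGLE_135": ("VI", False, True, True, False),
    "HPSGC_LIKE": ("VI", False, True, True, False),
}


@dataclass(frozen=True)
class ExprSimConfig:
    """Planted design for the expression generator.

    sigma is the residual log2 SD; effect the planted shift in log2
    units; class_counts must sum to n_genes.  ``var_prior_df``, when set,
    draws gene-wise variances from a scaled inverse-chi-square mixture
    with that many prior df (mean sigma^2) to exercise variance
    shrinkage; the default is a common variance.
    """

    seed: int
    n_genes: int = 2000
    reps: int = 3
    baseline_range: tuple[float, float] = (6.0, 12.0)
    sigma: float = 0.25
    effect: float = 2.0
    class_counts: dict = field(
        default_factory=lambda: dict(DEFAULT_CLASS_COUNTS)
    )
    var_prior_df: float | None = None

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.reps < 2:
            raise ValueError("reps must be >= 2")
        unknown = set(self.class_counts) - set(EXPR_CLASSES)
        if unknown:
            raise ValueError(f"unknown classes: {sorted(unknown)}")
        if any(c < 0 for c in self.class_counts.values()):
            raise ValueError("class counts must be >= 0")
        if sum(self.class_counts.values()) != self.n_genes:
            raise ValueError("class counts must sum to n_genes")


def simulate_expression(
    cfg: ExprSimConfig,
) -> tuple[ExpressionStudy, pd.DataFrame]:
    """Draw the study; returns (ExpressionStudy, truth table).

    value = baseline + class shift + N(0, sigma^2).  The truth table maps
    each gene to its class and the category / set memberships the
    pipeline is expected to recover.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = [f"SIM{i:05d}" for i in range(cfg.n_genes)]
    classes = np.repeat(
        [c for c in EXPR_CLASSES if cfg.class_counts.get(c, 0) > 0],
        [cfg.class_counts[c] for c in EXPR_CLASSES if cfg.class_counts.get(c, 0) > 0],
    )
    classes = classes[rng.permutation(cfg.n_genes)]

    sample_ids, design_rows = [], []
    for eco in ECOTYPES:
        for angle in ANGLES:
            for rep in range(1, cfg.reps + 1):
                sid = f"{eco.replace('-', '')}_{angle}_r{rep}"
                sample_ids.append(sid)
                design_rows.append(
                    {"sample_id": sid, "ecotype": eco, "angle_gp": angle, "replicate": rep}
                )
    design = pd.DataFrame(design_rows).set_index("sample_id")

    lo, hi = cfg.baseline_range
    baseline = rng.uniform(lo, hi, size=cfg.n_genes)
    if cfg.var_prior_df is not None:
        gene_sd = cfg.sigma * np.sqrt(
            cfg.var_prior_df / rng.chisquare(cfg.var_prior_df, size=cfg.n_genes)
        )
    else:
        gene_sd = np.full(cfg.n_genes, cfg.sigma)

    values = baseline[:, None] + rng.normal(size=(cfg.n_genes, len(sample_ids))) * gene_sd[:, None]
    cell_of_sample = [
        (design.loc[s, "ecotype"], int(design.loc[s, "angle_gp"])) for s in sample_ids
    ]
    for ci, cls in enumerate(classes):
        shifted = _CLASS_SHIFTS[cls]
        if not shifted:
            continue
        for j, cell in enumerate(cell_of_sample):
            if cell in shifted:
                values[ci, j] += cfg.effect

    study = ExpressionStudy(
        values=pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=sample_ids),
        design=design,
    )
    exp = [_CLASS_EXPECTATIONS[c] for c in classes]
    truth = pd.DataFrame(
        {
            "class": classes,
            "expected_category": [e[0] for e in exp],
            "expected_in_ws45": [e[1] for e in exp],
            "expected_in_ws135": [e[2] for e in exp],
            "expected_hpsgc": [e[3] for e in exp],
            "expected_removed": [e[4] for e in exp],
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return study, truth


# ---------------------------------------------------------------------------
# contrast-level planted set structure
# ---------------------------------------------------------------------------


def _contrast_table(
    genes: pd.Index, fc: np.ndarray, p: np.ndarray
) -> pd.DataFrame:
    q = bh_fdr(p)
    sig = (np.abs(fc) > 1.0) & (p < 0.05)
    return pd.DataFrame(
        {
            "log2fc": fc,
            "t": np.nan,
            "df": np.nan,
            "p": p,
            "q": q,
            "sig": sig,
            "sig_fdr": sig & (q < 0.05),
            "direction": np.where(fc > 0, "up", np.where(fc < 0, "down", "none")),
        },
        index=genes,
    )


def study_scale_comparison_matrix(
    n_genes: int = 500,
    effect: float = 2.0,
    cat_sizes: tuple[int, ...] = (61, 24, 43, 38, 26, 64),
    cat_up: tuple[int, ...] = (19, 15, 20, 30, 20, 14),
    n_inherent: int = 30,
    n_ws45: int = 66,
    n_ws135: int = 40,
    n_ws_shared: int = 14,
    n_overlap_45: int = 5,
    n_hpsgc_v: int = 3,
    n_hpsgc_vi: int = 8,
    n_col45: int = 22,
    n_col45_up: int = 3,
    n_col135: int = 6,
    n_col_shared: int = 4,
) -> tuple[ComparisonMatrix, dict]:
    """Synthetic comparison matrix with planted set-level structure.

    Contrast tables are written directly (members get |log2fc| = effect
    with p = 1e-4; everything else is null), so every downstream count is
    known exactly.  Defaults plant a configuration at the scale of a real
    two-ecotype, three-angle skewing survey: six between-ecotype category
    blocks with the stated up/down splits, an inherent-difference block
    (equal-magnitude, same-sign offsets at all three angles), within-WS DE
    sets of sizes ``n_ws45``/``n_ws135`` sharing ``n_ws_shared`` genes —
    one shared gene flips sign between angles — and an overlap set made of
    ``n_hpsgc_v + n_hpsgc_vi`` genes anchored at 135 degrees on both sides
    (the HPSGC) plus ``n_overlap_45`` Category-IV genes in the 45-degree
    within-WS set only.  Returns (matrix, expected-counts dict).
    """
    if n_hpsgc_v > cat_sizes[4] or n_hpsgc_vi > cat_sizes[5]:
        raise ValueError("HPSGC block exceeds its category size")
    hpsgc_total = n_hpsgc_v + n_hpsgc_vi
    ws135_only = n_ws135 - hpsgc_total - n_ws_shared
    ws45_only = n_ws45 - n_ws_shared - n_overlap_45
    if min(ws135_only, ws45_only) < 0:
        raise ValueError("within-WS set sizes inconsistent with overlap layout")

    genes = pd.Index([f"G{i:04d}" for i in range(n_genes)], name="gene_id")
    fc = {a: np.zeros(n_genes) for a in BETWEEN_ANGLES}
    pv = {a: np.full(n_genes, 0.9) for a in BETWEEN_ANGLES}
    within_fc = {
        ("Col-0", 45): np.zeros(n_genes),
        ("Col-0", 135): np.zeros(n_genes),
        ("WS", 45): np.zeros(n_genes),
        ("WS", 135): np.zeros(n_genes),
    }
    within_p = {k: np.full(n_genes, 0.9) for k in within_fc}

    cursor = 0

    def take(n: int) -> np.ndarray:
        nonlocal cursor
        idx = np.arange(cursor, cursor + n)
        cursor += n
        if cursor > n_genes:
            raise ValueError("gene universe too small for the requested blocks")
        return idx

    cat_angles = {
        "I": (90,),
        "II": (45, 90),
        "III": (90, 135),
        "IV": (45,),
        "V": (45, 135),
        "VI": (135,),
    }
    cat_blocks: dict[str, np.ndarray] = {}
    for name, size, up in zip(cat_angles, cat_sizes, cat_up):
        idx = take(size)
        cat_blocks[name] = idx
        signs = np.where(np.arange(size) < up, 1.0, -1.0)
        for a in cat_angles[name]:
            fc[a][idx] = signs * effect
            pv[a][idx] = 1e-4

    inherent = take(n_inherent)
    for a, mag in zip(BETWEEN_ANGLES, (1.5, 1.6, 1.4)):
        fc[a][inherent] = mag
        pv[a][inherent] = 1e-4

    # HPSGC genes: category V/VI blocks, also DE within WS at 135
    hpsgc_v = cat_blocks["V"][cat_sizes[4] - n_hpsgc_v:]
    hpsgc_vi = cat_blocks["VI"][cat_sizes[5] - n_hpsgc_vi:]  # drawn from the down block
    hpsgc = np.concatenate([hpsgc_v, hpsgc_vi])
    within_fc[("WS", 135)][hpsgc] = effect
    within_p[("WS", 135)][hpsgc] = 1e-4
    # the 45-degree-anchored overlap genes: category IV, within-WS 45 only
    overlap45 = cat_blocks["IV"][:n_overlap_45]
    within_fc[("WS", 45)][overlap45] = effect
    within_p[("WS", 45)][overlap45] = 1e-4

    shared = take(n_ws_shared)
    for key in (("WS", 45), ("WS", 135)):
        within_fc[key][shared] = -effect
        within_p[key][shared] = 1e-4
    # one shared gene responds in opposite directions at the two angles
    if n_ws_shared:
        within_fc[("WS", 45)][shared[0]] = -effect
        within_fc[("WS", 135)][shared[0]] = effect
    only45 = take(ws45_only)
    within_fc[("WS", 45)][only45] = -effect
    within_p[("WS", 45)][only45] = 1e-4
    only135 = take(ws135_only)
    within_fc[("WS", 135)][only135] = -effect
    within_p[("WS", 135)][only135] = 1e-4

    col_shared = take(n_col_shared)
    col45_unique = take(n_col45 - n_col_shared)
    col135_unique = take(n_col135 - n_col_shared)
    col45 = np.concatenate([col_shared, col45_unique])
    col45_signs = np.where(np.arange(n_col45) < n_col45_up, 1.0, -1.0)
    within_fc[("Col-0", 45)][col45] = col45_signs * effect
    within_p[("Col-0", 45)][col45] = 1e-4
    col135 = np.concatenate([col_shared, col135_unique])
    within_fc[("Col-0", 135)][col135] = -effect
    within_p[("Col-0", 135)][col135] = 1e-4

    within = {
        key: ContrastResult(
            contrast_id=within_contrast_id(*key),
            table=_contrast_table(genes, within_fc[key], within_p[key]),
        )
        for key in within_fc
    }
    between = {
        a: ContrastResult(
            contrast_id=between_contrast_id(a),
            table=_contrast_table(genes, fc[a], pv[a]),
        )
        for a in BETWEEN_ANGLES
    }
    expected = {
        "category_sizes": dict(zip(cat_angles, cat_sizes)),
        "genotype": sum(cat_sizes[3:]),
        "removed_inherent": n_inherent,
        "ws45": n_ws45,
        "ws135": n_ws135,
        "ws_shared": n_ws_shared,
        "ws_union": n_ws45 + n_ws135 - n_ws_shared,
        "overlap": hpsgc_total + n_overlap_45,
        "hpsgc": hpsgc_total,
        "cat6_down": cat_sizes[5] - cat_up[5],
        "col45": n_col45,
        "col45_up": n_col45_up,
        "col45_down": n_col45 - n_col45_up,
        "col135": n_col135,
        "col_shared": n_col_shared,
        "col45_unique": n_col45 - n_col_shared,
    }
    return ComparisonMatrix(within=within, between=between), expected
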