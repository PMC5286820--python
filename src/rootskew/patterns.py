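"""Candidate skew-gene inference from the seven-contrast comparison matrix.

Two overlapping routes identify genes associated with root skewing:

* the *physiology* route — genes whose transcription responds to the
  growth-plate angle within the skewing ecotype WS (45-vs-90 and
  135-vs-90 contrasts);
* the *genotype* route — genes differing between Col-0 and WS at each
  angle (log2fc = Col-0 minus WS, WS the reference), classified by their
  significance pattern across the three angles after removing inherent
  ecotype differences.

Between-ecotype genes significant at all three angles with near-constant
magnitude (span of the three log2fc values at most 1 log2 unit, same
sign) are constitutive differences between the accessions and are removed.
The remaining 2^3 significance patterns over (45, 90, 135) map onto six
categories:

    (F,T,F) -> I     90 only
    (T,T,F) -> II    90 and 45, same direction
    (F,T,T) -> III   90 and 135, same direction
    (T,F,F) -> IV    45 only
    (T,F,T) -> V     45 and 135, same direction
    (F,F,T) -> VI    135 only

(F,F,F) is NONE; a surviving (T,T,T) — or a two-angle pattern with
discordant directions — is OTHER and excluded from candidates.  The
genotype candidate set is IV u V u VI; the physiology set is the union of
the two within-WS DE sets.  Their intersection is the overlap set, and the
highly probable skew gene candidates (HPSGC) are the overlap genes whose
evidence involves the 135-degree angle on both sides: member of the
WS-135-vs-90 DE set AND Category V or VI.  The 135-degree plate elicits
skewing with minimal waving, so these genes track skewing free of the
waving confound.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffexpr import (
    BETWEEN_ANGLES,
    FC_CUT,
    P_CUT,
    Q_CUT,
    ContrastResult,
    ExpressionStudy,
    study_contrasts,
)

CATEGORIES = ("I", "II", "III", "IV", "V", "VI")
GENOTYPE_CATEGORIES = ("IV", "V", "VI")

_PATTERN_MAP = {
    (False, True, False): "I",
    (True, True, False): "II",
    (False, True, True): "III",
    (True, False, False): "IV",
    (True, False, True): "V",
    (False, False, True): "VI",
    (False, False, False): "NONE",
    (True, True, True): "OTHER",
}
# angles whose log2fc signs must agree ("altered in a same way")
_SIGN_PAIRS = {"II": (45, 90), "III": (90, 135), "V": (45, 135)}


@dataclass
class ComparisonMatrix:
    """All seven study contrasts over one gene universe."""

    within: dict[tuple[str, int], ContrastResult]
    between: dict[int, ContrastResult]

    def __post_init__(self) -> None:
        expected_within = {("Col-0", 45), ("Col-0", 135), ("WS", 45), ("WS", 135)}
        if set(self.within) != expected_within:
            raise ValueError(f"within contrasts must be {sorted(expected_within)}")
        if set(self.between) != set(BETWEEN_ANGLES):
            raise ValueError(f"between contrasts must cover angles {BETWEEN_ANGLES}")
        universes = {
            cid: frozenset(res.table.index)
            for cid, res in self.all_contrasts().items()
        }
        if len(set(universes.values())) != 1:
            raise ValueError("gene universe differs across contrasts")

    def all_contrasts(self) -> dict[str, ContrastResult]:
        out = {res.contrast_id: res for res in self.within.values()}
        out.update({res.contrast_id: res for res in self.between.values()})
        return out

    @property
    def genes(self) -> pd.Index:
        return next(iter(self.between.values())).table.index


def build_comparison_matrix(
    study: ExpressionStudy,
    moderated: bool = True,
    fc_cut: float = FC_CUT,
    p_cut: float = P_CUT,
    q_cut: float = Q_CUT,
) -> ComparisonMatrix:
    within, between = study_contrasts(
        study, moderated=moderated, fc_cut=fc_cut, p_cut=p_cut, q_cut=q_cut
    )
    return ComparisonMatrix(within=within, between=between)


def within_candidates(ws45: set, ws135: set) -> dict:
    """Set algebra over the two within-ecotype angle-responsive DE sets."""
    union = set(ws45) | set(ws135)
    shared = set(ws45) & set(ws135)
    return {
        "union": union,
        "shared": shared,
        "unique_45": set(ws45) - shared,
        "unique_135": set(ws135) - shared,
        "counts": {
            "n_45": len(ws45),
            "n_135": len(ws135),
            "shared": len(shared),
            "union": len(union),
            "unique_45": len(ws45) - len(shared),
            "unique_135": len(ws135) - len(shared),
        },
    }


def _between_frame(
    between: dict[int, ContrastResult], fc_cut: float, p_cut: float
) -> pd.DataFrame:
    genes = between[90].table.index
    df = pd.DataFrame(index=genes)
    for angle in BETWEEN_ANGLES:
        t = between[angle].table
        df[f"fc{angle}"] = t["log2fc"]
        df[f"sig{angle}"] = (t["log2fc"].abs() > fc_cut) & (t["p"] < p_cut)
    return df


def inherent_filter(
    between: dict[int, ContrastResult],
    span: float = 1.0,
    fc_cut: float = FC_CUT,
    p_cut: float = P_CUT,
) -> set:
    """Genes removed as constitutive (angle-independent) ecotype differences.

    Removed iff significant at all three angles, all three log2fc share
    one sign, and max(log2fc) - min(log2fc) <= span (default 1 log2 unit,
    the "within +/- 1 fold change on the log2 scale" rule).
    """
    df = _between_frame(between, fc_cut, p_cut)
    fc = df[[f"fc{a}" for a in BETWEEN_ANGLES]].to_numpy()
    sig_all = df[[f"sig{a}" for a in BETWEEN_ANGLES]].all(axis=1).to_numpy()
    same_sign = (np.sign(fc) == np.sign(fc[:, [0]])).all(axis=1) & (
        np.sign(fc[:, 0]) != 0
    )
    tight = (fc.max(axis=1) - fc.min(axis=1)) <= span
    return set(df.index[sig_all & same_sign & tight])


def categorize(
    between: dict[int, ContrastResult],
    removed: set | None = None,
    fc_cut: float = FC_CUT,
    p_cut: float = P_CUT,
    span: float = 1.0,
) -> pd.DataFrame:
    """Assign every gene exactly one category.

    Returns a frame indexed by gene with ``category`` in
    I..VI / OTHER / NONE / REMOVED_INHERENT plus the per-angle sig flags
    and log2fc values that justify the call.  Two-angle categories (II,
    III, V) require the two significant log2fc values to share a sign;
    discordant genes fall into OTHER.
    """
    if removed is None:
        removed = inherent_filter(between, span=span, fc_cut=fc_cut, p_cut=p_cut)
    df = _between_frame(between, fc_cut, p_cut)
    cats = []
    for gene, row in df.iterrows():
        if gene in removed:
            cats.append("REMOVED_INHERENT")
            continue
        pattern = (bool(row["sig45"]), bool(row["sig90"]), bool(row["sig135"]))
        cat = _PATTERN_MAP[pattern]
        if cat in _SIGN_PAIRS:
            a1, a2 = _SIGN_PAIRS[cat]
            if np.sign(row[f"fc{a1}"]) != np.sign(row[f"fc{a2}"]):
                cat = "OTHER"
        cats.append(cat)
    df = df.copy()
    df.insert(0, "category", cats)
    return df


def genotype_candidates(categories: pd.DataFrame) -> set:
    """Union of Categories IV, V and VI (the skew-indicative patterns)."""
    mask = categories["category"].isin(GENOTYPE_CATEGORIES)
    return set(categories.index[mask])


@dataclass
class CandidateReport:
    """Outcome of the two-route screen with per-gene provenance.

    ``provenance`` covers every gene admitted to any set: membership in
    the within-WS DE sets, its between-ecotype category, and flags for the
    overlap and HPSGC sets.
    """

    physiology_set: set
    genotype_set: set
    overlap_set: set
    hpsgc_set: set
    provenance: pd.DataFrame
    counts: dict

    def __post_init__(self) -> None:
        if not self.hpsgc_set <= self.overlap_set:
            raise ValueError("HPSGC set must be a subset of the overlap set")
        if not self.overlap_set <= (self.physiology_set & self.genotype_set):
            raise ValueError("overlap set must lie in physiology ∩ genotype")


def overlap_and_hpsgc(
    ws45: set,
    ws135: set,
    categories: pd.DataFrame,
) -> CandidateReport:
    """Intersect the physiology and genotype routes and apply the 135 anchor.

    overlap = (ws45 u ws135) n (IV u V u VI); HPSGC = overlap genes in the
    WS-135-vs-90 DE set whose category is V or VI, i.e. genes whose
    evidence involves the skew-only 135-degree condition on both sides.
    """
    within = within_candidates(ws45, ws135)
    physiology = within["union"]
    genotype = genotype_candidates(categories)
    overlap = physiology & genotype
    cat = categories["category"]
    hpsgc = {
        g for g in overlap if g in ws135 and cat.loc[g] in ("V", "VI")
    }
    admitted = sorted(physiology | genotype)
    prov = pd.DataFrame(
        {
            "in_ws45": [g in ws45 for g in admitted],
            "in_ws135": [g in ws135 for g in admitted],
            "category": [cat.loc[g] for g in admitted],
            "in_overlap": [g in overlap for g in admitted],
            "hpsgc": [g in hpsgc for g in admitted],
        },
        index=pd.Index(admitted, name="gene_id"),
    )
    counts = {
        "physiology": len(physiology),
        "genotype": len(genotype),
        "overlap": len(overlap),
        "hpsgc": len(hpsgc),
        "within_ws": within["counts"],
        "per_category": cat.value_counts().to_dict(),
    }
    return CandidateReport(
        physiology_set=physiology,
        genotype_set=genotype,
        overlap_set=overlap,
        hpsgc_set=hpsgc,
        provenance=prov,
        counts=counts,
    )


def count_summary(
    contrasts: dict[str, ContrastResult],
    fc_cut: float = FC_CUT,
    p_cut: float = P_CUT,
) -> pd.DataFrame:
    """Up/down/total called genes per contrast (total = up + down)."""
    rows = []
    for cid, res in contrasts.items():
        t = res.table
        sig = (t["log2fc"].abs() > fc_cut) & (t["p"] < p_cut)
        up = int((sig & (t["log2fc"] > 0)).sum())
        down = int((sig & (t["log2fc"] < 0)).sum())
        rows.append({"contrast_id": cid, "up": up, "down": down, "total": up + down})
    return pd.DataFrame(rows)


def run_pipeline(
    matrix: ComparisonMatrix,
    fc_cut: float = FC_CUT,
    p_cut: float = P_CUT,
    span: float = 1.0,
) -> dict:
    """Full candidate screen from a comparison matrix.

    Returns {"categories", "report", "counts", "removed"}.
    """
    removed = inherent_filter(
        matrix.between, span=span, fc_cut=fc_cut, p_cut=p_cut
    )
    categories = categorize(
        matrix.between, removed=removed, fc_cut=fc_cut, p_cut=p_cut, span=span
    )
    ws45 = {
        g
        for g, s in _sig_series(matrix.within[("WS", 45)], fc_cut, p_cut).items()
        if s
    }
    ws135 = {
        g
        for g, s in _sig_series(matrix.within[("WS", 135)], fc_cut, p_cut).items()
        if s
    }
    report = overlap_and_hpsgc(ws45, ws135, categories)
    counts = count_summary(matrix.all_contrasts(), fc_cut=fc_cut, p_cut=p_cut)
    return {
        "categories": categories,
        "report": report,
        "counts": counts,
        "removed": removed,
    }


def _sig_series(res: ContrastResult, fc_cut: float, p_cut: float) -> pd.Series:
    t = res.table
    return (t["log2fc"].abs() > fc_cut) & (t["p"] < p_cut)
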