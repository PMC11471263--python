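"""Post-processing of in-silico mutational-scanning score tables.

Score tables arrive as long-form CSV (position x 20 amino acids) from
external scorers -- an energy-based point-mutant scan ("rosetta_pmut"), an
antibody language model's pseudo-log-likelihoods ("antiberty_pll"), or a
missense-effect predictor for the C region ("alphamissense").  This module
pivots them into matrices, rescales scores relative to the wild-type
residue at each position (so a scaled score reads as the preference change
of the substitution over WT), sums scaled language-model scores into
additive multi-mutant estimates, and compares scans of the same V region
carried by different constant regions to locate isotype-sensitive
positions.

Energy-based point-mutant scores are computed per mutation in isolation
and are not additive; :func:`multi_mutant_score` therefore refuses
"rosetta_pmut"-tagged matrices unless forced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ArgumentError, ParseError, ScaleError

AA20 = list("ACDEFGHIKLMNPQRSTVWY")
NON_ADDITIVE_TAGS = {"rosetta_pmut"}
EFFECT_EPS = 1e-6


@dataclass
class ScoreMatrix:
    """Per-position x 20-amino-acid mutational scores.

    ``scores`` is indexed by position label with one column per amino
    acid; missing values stay NaN (never silently zero).  ``wt`` maps each
    position to its wild-type residue.  ``scaled`` records whether scores
    are WT-relative.
    """

    scores: pd.DataFrame
    wt: pd.Series
    scorer_tag: str
    scaled: bool = False

    @property
    def positions(self) -> list[str]:
        return list(self.scores.index)

    def validate(self) -> None:
        if list(self.scores.columns) != AA20:
            raise ValueError("score matrix must have exactly the 20 standard "
                             "amino-acid columns")
        if self.scaled:
            for pos in self.scores.index:
                val = self.scores.at[pos, self.wt[pos]]
                if not np.isclose(val, 0.0, atol=1e-12):
                    raise ValueError(f"scaled matrix has non-zero WT score at {pos}")


def parse_scores(path, scorer_tag: str) -> ScoreMatrix:
    """Read a long-form score CSV (position_label, wt_aa, mut_aa, score)."""
    try:
        df = pd.read_csv(path, dtype={"position_label": str, "wt_aa": str,
                                      "mut_aa": str})
    except Exception as exc:
        raise ParseError(f"{path}: cannot read CSV: {exc}") from exc
    required = ["position_label", "wt_aa", "mut_aa", "score"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    if not pd.api.types.is_numeric_dtype(df["score"]):
        bad = df.loc[pd.to_numeric(df["score"], errors="coerce").isna(), "score"]
        raise ParseError(f"{path}: non-numeric score value(s), e.g. {bad.iloc[0]!r}")
    dup = df.duplicated(subset=["position_label", "mut_aa"], keep=False)
    if dup.any():
        pairs = df.loc[dup, ["position_label", "mut_aa"]].drop_duplicates()
        raise ParseError(f"{path}: duplicate (position, mutation) rows: "
                         f"{pairs.values.tolist()[:5]}")
    wt_per_pos = df.groupby("position_label", sort=False)["wt_aa"].nunique()
    if (wt_per_pos > 1).any():
        raise ParseError(f"{path}: conflicting wt_aa within position(s) "
                         f"{list(wt_per_pos[wt_per_pos > 1].index)}")
    order = df["position_label"].drop_duplicates().tolist()
    pivot = df.pivot(index="position_label", columns="mut_aa", values="score")
    pivot = pivot.reindex(index=order, columns=AA20)
    wt = df.drop_duplicates("position_label").set_index("position_label")["wt_aa"]
    wt = wt.reindex(order)
    bad_wt = wt[~wt.isin(AA20)]
    if len(bad_wt):
        raise ParseError(f"{path}: invalid wt_aa {bad_wt.iloc[0]!r}")
    return ScoreMatrix(scores=pivot, wt=wt, scorer_tag=scorer_tag, scaled=False)


def write_scores(matrix: ScoreMatrix, path) -> None:
    """Write the long-form CSV that :func:`parse_scores` reads."""
    rows = []
    for pos in matrix.positions:
        for aa in AA20:
            val = matrix.scores.at[pos, aa]
            if np.isnan(val):
                continue
            rows.append((pos, matrix.wt[pos], aa, val))
    out = pd.DataFrame(rows, columns=["position_label", "wt_aa", "mut_aa", "score"])
    out.to_csv(path, index=False, float_format="%.6g")


def scale_to_wt(raw: ScoreMatrix) -> ScoreMatrix:
    """Subtract each position's wild-type score: WT cells become exactly 0."""
    if raw.scaled:
        raise ScaleError("matrix is already WT-scaled")
    wt_scores = []
    for pos in raw.positions:
        val = raw.scores.at[pos, raw.wt[pos]]
        if np.isnan(val):
            raise ScaleError(f"missing WT score at position {pos}")
        wt_scores.append(val)
    scaled = raw.scores.sub(pd.Series(wt_scores, index=raw.scores.index), axis=0)
    return ScoreMatrix(scores=scaled, wt=raw.wt.copy(), scorer_tag=raw.scorer_tag,
                       scaled=True)


def multi_mutant_score(scaled: ScoreMatrix,
                       mutations: list[tuple[str, str]],
                       force: bool = False) -> float:
    """Additive multi-mutant score: sum of scaled single-mutation scores.

    Positive means the combination is preferable relative to WT.  Assumes
    the mutations act independently (no compensatory coupling); refuses
    non-additive (energy-based point-scan) score tables unless ``force``.
    """
    if not scaled.scaled:
        raise ArgumentError("multi_mutant_score requires a WT-scaled matrix")
    if scaled.scorer_tag in NON_ADDITIVE_TAGS and not force:
        raise ArgumentError(
            f"scores tagged {scaled.scorer_tag!r} are computed per mutation in "
            "isolation and are not additive; pass force=True to sum anyway")
    seen: set[str] = set()
    total = 0.0
    for pos, aa in mutations:
        if pos in seen:
            raise ArgumentError(f"duplicate position {pos!r} in mutation list")
        seen.add(pos)
        if pos not in scaled.scores.index:
            raise ArgumentError(f"unknown position label {pos!r}")
        if aa not in AA20:
            raise ArgumentError(f"unknown amino acid {aa!r}")
        if aa == scaled.wt[pos]:
            raise ArgumentError(f"{pos}{aa} is the wild-type residue")
        val = scaled.scores.at[pos, aa]
        if np.isnan(val):
            raise ArgumentError(f"no score for {pos}->{aa}")
        total += float(val)
    return total


def isotype_sensitivity(scores_iso_a: ScoreMatrix,
                        scores_iso_b: ScoreMatrix,
                        scores_control: ScoreMatrix,
                        eps: float = EFFECT_EPS,
                        effect_method: str = "mean_abs") -> pd.DataFrame:
    """Per-position isotype-sensitivity statistics for a shared V region.

    The three matrices score the same V-region positions in the context of
    isotype A (e.g. IgA1), isotype B (e.g. IgG1), and a second structure
    of isotype B serving as the within-isotype control.  Per position,
    over the <= 19 non-WT substitutions m:

        d_iso(m)  = score_a(p, m) - score_b(p, m)
        d_ctrl(m) = score_control(p, m) - score_b(p, m)

    The effect is a signed log2 fold difference of the between-isotype over
    the within-isotype comparison.  ``effect_method="mean_abs"`` (default)
    uses log2((mean|d_iso| + eps) / (mean|d_ctrl| + eps)) signed by the
    mean of d_iso (negative = isotype-A-favorable); ``"mean"`` uses the
    ratio of the absolute mean differences signed by their gap,
    sign(mean d_iso - mean d_ctrl) * log2((|mean d_iso| + eps) /
    (|mean d_ctrl| + eps)).  Significance per position is a two-sided
    Wilcoxon signed-rank test of d_iso against d_ctrl, corrected across
    positions with Benjamini-Hochberg.

    Returns a volcano-plot-ready frame with columns position, wt_aa,
    effect, p_value, q_value, n_substitutions, note.
    """
    if effect_method not in ("mean_abs", "mean"):
        raise ValueError(f"unknown effect_method {effect_method!r}")
    mats = (scores_iso_a, scores_iso_b, scores_control)
    if len({m.scaled for m in mats}) != 1:
        raise ArgumentError("all three matrices must be uniformly scaled or raw")
    shared = [p for p in scores_iso_a.positions
              if p in set(scores_iso_b.positions) and p in set(scores_control.positions)]
    if not shared:
        raise ArgumentError("no shared position labels across the three matrices")
    for p in shared:
        wts = {m.wt[p] for m in mats}
        if len(wts) != 1:
            raise ArgumentError(f"mismatched WT residues at position {p}: {sorted(wts)}")

    rows = []
    for p in shared:
        wt = scores_iso_a.wt[p]
        subs = [aa for aa in AA20 if aa != wt]
        a = scores_iso_a.scores.loc[p, subs].to_numpy(dtype=float)
        b = scores_iso_b.scores.loc[p, subs].to_numpy(dtype=float)
        c = scores_control.scores.loc[p, subs].to_numpy(dtype=float)
        ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
        n = int(ok.sum())
        if n < 2:
            rows.append((p, wt, np.nan, np.nan, n,
                         "skipped: fewer than 2 substitutions with all three scores"))
            continue
        d_iso = a[ok] - b[ok]
        d_ctrl = c[ok] - b[ok]
        if effect_method == "mean_abs":
            mag = np.log2((np.abs(d_iso).mean() + eps) / (np.abs(d_ctrl).mean() + eps))
            sign = np.sign(d_iso.mean())
            # sign carries favourability, magnitude the fold difference
            effect = float(sign * mag) if sign != 0 else 0.0
        else:
            m_iso, m_ctrl = d_iso.mean(), d_ctrl.mean()
            sign = np.sign(m_iso - m_ctrl)
            effect = float(sign * np.log2((abs(m_iso) + eps) / (abs(m_ctrl) + eps)))
        diff = d_iso - d_ctrl
        if np.allclose(diff, 0.0):
            p_val = 1.0
        else:
            p_val = float(stats.wilcoxon(d_iso, d_ctrl,
                                         alternative="two-sided").pvalue)
        rows.append((p, wt, effect, p_val, n, ""))

    out = pd.DataFrame(rows, columns=["position", "wt_aa", "effect", "p_value",
                                      "n_substitutions", "note"])
    out["q_value"] = np.nan
    tested = out["p_value"].notna()
    if tested.any():
        out.loc[tested, "q_value"] = multipletests(
            out.loc[tested, "p_value"].to_numpy(), method="fdr_bh")[1]
    return out[["position", "wt_aa", "effect", "p_value", "q_value",
                "n_substitutions", "note"]]
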