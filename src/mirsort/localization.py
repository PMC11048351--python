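"""Classify miRNAs as preferentially secreted (sEV), cellular, or neutral.

The compartment profiles are reduced to percentage composition (each
miRNA's signal over the summed signals of all reliably detected miRNAs in
the same replicate), compared with an unpaired equal-variance two-sided
t-test, and corrected with the adaptive two-stage Benjamini-Krieger-
Yekutieli (BKY) linear step-up FDR procedure. A miRNA detected in only one
compartment carries composition 0 in the other.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import AbundanceProfile, SequenceSet

CALLS = ("SEV_ENRICHED", "CELL_ENRICHED", "NEUTRAL", "UNDETECTED")


# ---------------------------------------------------------------------------
# Detection and composition
# ---------------------------------------------------------------------------


def detect_reliable(
    profile: AbundanceProfile, alpha: float = 0.05, rule: str = "all"
) -> set[str]:
    """miRNAs reliably detected above background in a compartment.

    ``rule="all"`` (default) requires DABG p < alpha in every replicate;
    ``rule="any"`` in at least one.
    """
    below = profile.detection_p < alpha
    if rule == "all":
        mask = below.all(axis=1)
    elif rule == "any":
        mask = below.any(axis=1)
    else:
        raise ValueError(f"unknown detection rule {rule!r}")
    return {m for m, ok in zip(profile.mirna_ids, mask) if ok}


def composition(profile: AbundanceProfile, detected: Iterable[str]) -> pd.DataFrame:
    """Per-replicate fractional composition of the detected miRNAs.

    Each replicate column of the result sums to 1: a miRNA's signal divided
    by the total signal of all reliably detected miRNAs in that replicate.
    """
    detected = set(detected)
    unknown = detected - set(profile.mirna_ids)
    if unknown:
        raise KeyError(f"detected ids not in profile: {sorted(unknown)[:5]}")
    ids = [m for m in profile.mirna_ids if m in detected]
    rows = [profile.row(m) for m in ids]
    sig = profile.signals[rows]
    totals = sig.sum(axis=0)
    zero = np.nonzero(totals == 0)[0]
    if zero.size:
        raise ValueError(
            f"{profile.compartment} replicate {zero[0] + 1}: "
            "total reliable signal is zero"
        )
    return pd.DataFrame(
        sig / totals,
        index=ids,
        columns=[f"rep{j + 1}" for j in range(profile.n_replicates)],
    )


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


class TTestResult(NamedTuple):
    t_stat: float
    p_value: float


def equal_variance_ttest(x, y) -> TTestResult:
    """Unpaired two-sided Student t-test with pooled (equal) variance.

    Degenerate inputs are defined explicitly: zero pooled variance with
    equal means gives (t=0, p=1); zero pooled variance with unequal means
    gives (t=+-inf, p=0).
    """
    t, p = _ttest_rows(np.atleast_2d(np.asarray(x, float)),
                       np.atleast_2d(np.asarray(y, float)))
    return TTestResult(float(t[0]), float(p[0]))


def _ttest_rows(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise pooled-variance t; x and y are (n_tests, nx) and (n_tests, ny)."""
    nx, ny = x.shape[1], y.shape[1]
    if nx < 2 or ny < 2:
        raise ValueError("each group needs at least 2 observations")
    mx, my = x.mean(axis=1), y.mean(axis=1)
    vx = x.var(axis=1, ddof=1)
    vy = y.var(axis=1, ddof=1)
    df = nx + ny - 2
    sp2 = ((nx - 1) * vx + (ny - 1) * vy) / df
    se = np.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    diff = mx - my
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    # zero pooled variance: exact-equality comparisons define the verdict
    degenerate = se == 0
    t = np.where(degenerate & (diff == 0), 0.0, t)
    signed_inf = np.where(diff > 0, np.inf, -np.inf)
    t = np.where(degenerate & (diff != 0), signed_inf, t)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isinf(t), 0.0, p)
    return t, np.clip(p, 0.0, 1.0)


def _bh_adjusted(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


class FdrResult(NamedTuple):
    q_values: np.ndarray
    reject: np.ndarray


def fdr_bky_two_stage(p_values, q: float = 0.05) -> FdrResult:
    """Two-stage adaptive linear step-up FDR (Benjamini-Krieger-Yekutieli).

    Stage 1 runs BH at q' = q/(1+q); with r1 rejections the null count is
    estimated as m0 = m - r1. If r1 is 0 nothing is rejected; if r1 = m
    everything is. Otherwise stage 2 runs BH at q'' = q' * m / m0 and its
    rejection set is returned.

    ``q_values`` are adjusted so that (q_i <= q) holds exactly when miRNA i
    is rejected by the procedure run at level q, for any level in (0, 1].
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        return FdrResult(np.array([]), np.array([], dtype=bool))
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return FdrResult(_bky_qvalues(p), _bky_reject(p, q))


def _bky_reject(p: np.ndarray, q: float) -> np.ndarray:
    m = p.size
    c1 = q / (1.0 + q)
    padj = _bh_adjusted(p)
    r1 = int(np.sum(padj <= c1))
    if r1 == 0:
        return np.zeros(m, dtype=bool)
    if r1 == m:
        return np.ones(m, dtype=bool)
    return padj <= c1 * m / (m - r1)


def _bky_qvalues(p: np.ndarray) -> np.ndarray:
    """Smallest level at which each p-value is rejected by the two-stage rule.

    Works on the scale c = q/(1+q). For stage-1 rejection count r (constant
    on c in [t_{r-1}, t_r) where t is the sorted vector of BH-adjusted
    p-values) index i is rejected iff padj_i * (m-r)/m <= c; the infimum
    over feasible intervals converts back through q = c/(1-c).
    """
    m = p.size
    padj = _bh_adjusted(p)
    t = np.sort(padj)
    v = padj[:, None]
    if m > 1:
        r = np.arange(1, m)  # stage-1 rejection counts with a finite interval
        cand = np.maximum(t[None, :-1], v * (m - r)[None, :] / m)
        feasible = cand < t[None, 1:]
        cand = np.where(feasible, cand, np.inf)
        c_star = np.minimum(cand.min(axis=1), t[-1])  # t[-1]: reject-all region
    else:
        c_star = np.full(1, t[-1])
    with np.errstate(divide="ignore"):
        qv = c_star / (1.0 - c_star)
    qv = np.where(c_star >= 1.0, np.inf, qv)
    return np.minimum(qv, 1.0)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


@dataclass
class LocalizationTable:
    """Per-miRNA composition summary, test results, and 3-way class call."""

    table: pd.DataFrame  # index mirna_id
    q_threshold: float = 0.05

    COLUMNS = ("mean_comp_cell", "mean_comp_sev", "t_stat", "p_value", "q_value", "call")

    def members(self, call: str) -> list[str]:
        if call not in CALLS:
            raise ValueError(f"unknown call {call!r}")
        return list(self.table.index[self.table["call"] == call])

    @property
    def counts(self) -> dict[str, int]:
        return {c: int((self.table["call"] == c).sum()) for c in CALLS}

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="mirna_id")

    @classmethod
    def from_tsv(cls, path: str | Path, q_threshold: float = 0.05) -> "LocalizationTable":
        df = pd.read_csv(path, sep="\t", index_col="mirna_id")
        return cls(df[list(cls.COLUMNS)], q_threshold)


def align_profiles(
    cell: AbundanceProfile, sev: AbundanceProfile
) -> list[str]:
    """Union of miRNA ids, cell order first, then sEV-only ids in sEV order."""
    cell_set = set(cell.mirna_ids)
    return list(cell.mirna_ids) + [m for m in sev.mirna_ids if m not in cell_set]


def classify_localization(
    cell: AbundanceProfile,
    sev: AbundanceProfile,
    q: float = 0.05,
    dabg_alpha: float = 0.05,
    detection_rule: str = "all",
) -> LocalizationTable:
    """Full localization pipeline: detect, compose, test, correct, call.

    The union of the two detected sets is tested; the per-miRNA test
    compares the sEV replicate compositions against the cell replicate
    compositions, with composition 0 in a compartment where the miRNA was
    not reliably detected. Significance direction follows the sign of
    mean(sEV composition) - mean(cell composition).
    """
    if cell.compartment != "CELL" or sev.compartment != "SEV":
        raise ValueError("profiles must be labelled CELL and SEV respectively")
    ids = align_profiles(cell, sev)
    det_cell = detect_reliable(cell, dabg_alpha, detection_rule)
    det_sev = detect_reliable(sev, dabg_alpha, detection_rule)

    n = len(ids)
    comp_cell = np.zeros((n, cell.n_replicates))
    comp_sev = np.zeros((n, sev.n_replicates))
    if det_cell:
        cc = composition(cell, det_cell)
        idx = {m: i for i, m in enumerate(ids)}
        comp_cell[[idx[m] for m in cc.index]] = cc.to_numpy()
    if det_sev:
        cs = composition(sev, det_sev)
        idx = {m: i for i, m in enumerate(ids)}
        comp_sev[[idx[m] for m in cs.index]] = cs.to_numpy()

    tested = np.array([(m in det_cell) or (m in det_sev) for m in ids])
    t_stat = np.full(n, np.nan)
    p_value = np.full(n, np.nan)
    q_value = np.full(n, np.nan)
    if tested.any():
        t_sub, p_sub = _ttest_rows(comp_sev[tested], comp_cell[tested])
        q_sub, rej_sub = fdr_bky_two_stage(p_sub, q)
        t_stat[tested], p_value[tested], q_value[tested] = t_sub, p_sub, q_sub

    mean_cell = comp_cell.mean(axis=1)
    mean_sev = comp_sev.mean(axis=1)
    call = np.where(
        ~tested,
        "UNDETECTED",
        np.where(
            (q_value < q) & (mean_sev > mean_cell),
            "SEV_ENRICHED",
            np.where((q_value < q) & (mean_sev < mean_cell), "CELL_ENRICHED", "NEUTRAL"),
        ),
    )
    df = pd.DataFrame(
        {
            "mean_comp_cell": mean_cell,
            "mean_comp_sev": mean_sev,
            "t_stat": t_stat,
            "p_value": p_value,
            "q_value": q_value,
            "call": call,
        },
        index=pd.Index(ids, name="mirna_id"),
    )
    return LocalizationTable(df, q_threshold=q)


# ---------------------------------------------------------------------------
# Sequence statistics by class
# ---------------------------------------------------------------------------


def au_fraction(seq: str) -> float:
    """Fraction of A and U bases in an RNA sequence."""
    return (seq.count("A") + seq.count("U")) / len(seq)


@dataclass
class ClassSequenceStats:
    per_class: pd.DataFrame  # class, n, mean_au_fraction, mean_length
    tests: pd.DataFrame      # statistic, t_stat, p_value, note


def compare_class_sequence_stats(
    table: LocalizationTable, seqs: SequenceSet
) -> ClassSequenceStats:
    """AU% and length per localization class, with SEV-vs-CELL t-tests.

    Mirrors the observation that secreted miRNAs tend to be GC-richer while
    their lengths do not differ. Classes with fewer than 2 sequenced members
    report their statistic but skip the test with a notice.
    """
    values: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    rows = []
    for cls in ("SEV_ENRICHED", "CELL_ENRICHED", "NEUTRAL"):
        members = [m for m in table.members(cls) if m in seqs.records]
        au = np.array([au_fraction(seqs.records[m]) for m in members])
        ln = np.array([len(seqs.records[m]) for m in members], dtype=float)
        values[cls] = (au, ln)
        rows.append(
            {
                "class": cls,
                "n": len(members),
                "mean_au_fraction": au.mean() if len(members) else np.nan,
                "mean_length": ln.mean() if len(members) else np.nan,
            }
        )
    tests = []
    for name, idx in (("au_fraction", 0), ("length", 1)):
        a = values["SEV_ENRICHED"][idx]
        b = values["CELL_ENRICHED"][idx]
        if len(a) < 2 or len(b) < 2:
            tests.append(
                {"statistic": name, "t_stat": np.nan, "p_value": np.nan,
                 "note": "skipped: class with < 2 members"}
            )
        else:
            t, p = equal_variance_ttest(a, b)
            tests.append({"statistic": name, "t_stat": t, "p_value": p, "note": ""})
    return ClassSequenceStats(pd.DataFrame(rows), pd.DataFrame(tests))
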