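"""Synthetic two-compartment miRNA datasets with known ground truth.

Emulates the structure of a replicated microarray comparison of
intracellular versus small-extracellular-vesicle (sEV) miRNA content:
log-normal baseline abundances, compartment-specific composition shifts for
designated sEV-/cell-enriched subsets, multiplicative log-normal replicate
noise, detected-above-background p-values, ~22-nt sequences whose base
composition can be GC-shifted in the secreted class, and RBP motif
consensus strings planted preferentially into the enriched subsets. Every
quantity derives from a seeded generator, so outputs are byte-identical
under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .io_formats import RNA_BASES, AbundanceProfile, MotifModel, SequenceSet
from .localization import LocalizationTable
from .motif_enrichment import MotifEnrichmentResult
from .prediction import CVReport, auc_score

#: Decoy motif PFMs are drawn from their own fixed stream so the decoy
#: collection is identical across simulation seeds.
DECOY_SEED = 857_2024

PlantedMotif = tuple[str, float, float]  # consensus, rate in sEV class, rate in cell class

# Default plantings: a GC-rich motif preferentially in the secreted class
# (AGGGA, the consensus recognized by NONO/HNRNPA2B1-like readers) and a
# pyrimidine-rich one in the retained class.
DEFAULT_PLANTED: tuple[PlantedMotif, ...] = (
    ("AGGGA", 0.8, 0.05),
    ("UCUUC", 0.05, 0.8),
)


@dataclass
class SimulationConfig:
    """Study-shape parameters of the synthetic dataset.

    Defaults echo the observed shape of a neuronal microarray comparison:
    527 miRNAs detected intracellularly, 129 in sEVs, three replicates per
    compartment, and roughly 15% / 45% of miRNAs preferentially secreted /
    retained. Effect size is a composition fold change (default 4) with 20%
    multiplicative log-normal replicate noise.
    """

    n_mirna: int = 527
    n_sev_detected: int = 129
    n_replicates: int = 3
    frac_sev_enriched: float = 0.15
    frac_cell_enriched: float = 0.45
    fold_change: float = 4.0
    noise_cv: float = 0.2
    baseline_sigma: float = 1.5  # log-normal spread of baseline abundances
    planted_motifs: tuple[PlantedMotif, ...] = DEFAULT_PLANTED
    n_decoy_motifs: int = 20
    gc_bias: bool = True
    seq_len_min: int = 18
    seq_len_max: int = 25
    dabg_detected_max: float = 0.04
    dabg_undetected_min: float = 0.1
    cell_total_signal: float = 1e6
    sev_total_signal: float = 2e5
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_mirna <= 0 or self.n_replicates < 2:
            raise ValueError("counts must be positive (>= 2 replicates)")
        if not 0 < self.n_sev_detected <= self.n_mirna:
            raise ValueError("n_sev_detected must be in (0, n_mirna]")
        if self.frac_sev_enriched + self.frac_cell_enriched > 1:
            raise ValueError("class fractions must sum to <= 1")
        if round(self.frac_sev_enriched * self.n_mirna) > self.n_sev_detected:
            raise ValueError(
                "infeasible: more sEV-enriched miRNAs than sEV-detected slots"
            )
        for consensus, rp, rb in self.planted_motifs:
            if not 0 <= rp <= 1 or not 0 <= rb <= 1:
                raise ValueError("plant rates must lie in [0, 1]")
            if len(consensus) > self.seq_len_min:
                raise ValueError(
                    f"planted motif {consensus!r} is longer than the shortest sequence"
                )
        if self.fold_change <= 0 or self.noise_cv < 0:
            raise ValueError("fold_change must be positive, noise_cv non-negative")


def null_config(seed: int = 1, **overrides) -> SimulationConfig:
    """A genuinely null dataset: no composition effect, no sequence bias,
    full detection in both compartments (one-sided detection is itself a
    composition difference, so the null removes it)."""
    base = dict(
        fold_change=1.0,
        gc_bias=False,
        n_sev_detected=overrides.get("n_mirna", 527),
        planted_motifs=(),
        seed=seed,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@dataclass
class GroundTruth:
    """Planted truth: per-miRNA class and per-motif target class (or None)."""

    mirna_class: dict[str, str]
    motif_targets: dict[str, str | None]


class SimulationResult(NamedTuple):
    cell: AbundanceProfile
    sev: AbundanceProfile
    seqs: SequenceSet
    motifs: list[MotifModel]
    truth: GroundTruth


# ---------------------------------------------------------------------------
# Motif construction
# ---------------------------------------------------------------------------


def consensus_to_pfm(consensus: str, weak_prob: float = 0.55) -> np.ndarray:
    """PFM from a consensus string; uppercase positions are deterministic,
    lowercase mark weakly preferred positions (probability ``weak_prob``,
    remainder spread over the other bases)."""
    rows = []
    for ch in consensus:
        base = ch.upper().replace("T", "U")
        if base not in RNA_BASES:
            raise ValueError(f"bad consensus character {ch!r}")
        row = np.zeros(4)
        if ch.isupper():
            row[RNA_BASES.index(base)] = 1.0
        else:
            row[:] = (1.0 - weak_prob) / 3.0
            row[RNA_BASES.index(base)] = weak_prob
        rows.append(row)
    return np.array(rows)


def random_decoy_motifs(
    n: int, seed: int = DECOY_SEED, width_range: tuple[int, int] = (4, 8),
    species: str = "Mus musculus",
) -> list[MotifModel]:
    """Random Dirichlet PFMs used as non-planted competitor motifs."""
    rng = np.random.default_rng(seed)
    motifs = []
    for i in range(n):
        w = int(rng.integers(width_range[0], width_range[1] + 1))
        pfm = rng.dirichlet(np.full(4, 0.5), size=w)
        motifs.append(
            MotifModel(f"decoy_{i + 1:02d}", f"DECOY{i + 1:02d}", species, pfm)
        )
    return motifs


def fixture_motifs(n_decoys: int = 17) -> list[MotifModel]:
    """A no-download motif collection: consensus PFMs for three RBPs with
    published binding preferences (NONO AGGGA, HNRNPA2B1 uAGGGA with a weak
    first position, FUS GGUG) plus seeded decoys."""
    named = [
        MotifModel("fix_NONO", "NONO", "Mus musculus", consensus_to_pfm("AGGGA")),
        MotifModel("fix_HNRNPA2B1", "HNRNPA2B1", "Mus musculus",
                   consensus_to_pfm("uAGGGA")),
        MotifModel("fix_FUS", "FUS", "Mus musculus", consensus_to_pfm("GGUG")),
    ]
    return named + random_decoy_motifs(n_decoys)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def _lognormal_noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Multiplicative noise with unit mean and coefficient of variation cv."""
    if cv == 0:
        return np.ones(shape)
    sigma2 = np.log1p(cv * cv)
    return np.exp(rng.normal(-sigma2 / 2.0, np.sqrt(sigma2), size=shape))


def _class_base_probs(cls: str, gc_bias: bool) -> np.ndarray:
    if not gc_bias:
        return np.full(4, 0.25)
    au = {"SEV_ENRICHED": 0.40, "CELL_ENRICHED": 0.60, "NEUTRAL": 0.50}[cls]
    gc = 1.0 - au
    return np.array([au / 2, gc / 2, gc / 2, au / 2])  # A C G U


def simulate(config: SimulationConfig) -> SimulationResult:
    """Generate aligned CELL/SEV profiles, sequences, motifs, and truth."""
    rng = np.random.default_rng(config.seed)
    n = config.n_mirna
    ids = [f"syn-miR-{i + 1:04d}" for i in range(n)]

    # --- true classes -----------------------------------------------------
    n_sev = int(round(config.frac_sev_enriched * n))
    n_cell = int(round(config.frac_cell_enriched * n))
    classes = np.array(
        ["SEV_ENRICHED"] * n_sev + ["CELL_ENRICHED"] * n_cell
        + ["NEUTRAL"] * (n - n_sev - n_cell)
    )
    rng.shuffle(classes)
    truth_class = dict(zip(ids, classes))

    # --- compositions -----------------------------------------------------
    # Compositions are closed (they sum to 1), so a planted fold change
    # cannot hold for every miRNA simultaneously. Neutral miRNAs are pinned
    # to exactly equal compositions in both compartments and the closure
    # factor k is absorbed by the two enriched classes alone: their mutual
    # contrast stays exactly fold_change**2 for every seed.
    w = rng.lognormal(mean=0.0, sigma=config.baseline_sigma, size=n)
    comp_cell_true = w / w.sum()
    mult = np.where(
        classes == "SEV_ENRICHED", config.fold_change,
        np.where(classes == "CELL_ENRICHED", 1.0 / config.fold_change, 1.0),
    )
    neutral = classes == "NEUTRAL"
    comp_sev_true = comp_cell_true * mult
    enriched_mass = comp_sev_true[~neutral].sum()
    if enriched_mass > 0:
        k = (1.0 - comp_cell_true[neutral].sum()) / enriched_mass
        comp_sev_true = np.where(neutral, comp_cell_true, comp_sev_true * k)
    w_cell = comp_cell_true
    w_sev = comp_sev_true

    # sEV detection: every planted sEV-enriched miRNA is detectable there;
    # remaining slots go to the highest sEV abundances.
    sev_detected = np.zeros(n, dtype=bool)
    sev_idx = np.nonzero(classes == "SEV_ENRICHED")[0]
    sev_detected[sev_idx] = True
    remaining = config.n_sev_detected - sev_idx.size
    others = np.nonzero(~sev_detected)[0]
    take = others[np.argsort(w_sev[others], kind="stable")[::-1][:remaining]]
    sev_detected[take] = True

    reps = config.n_replicates
    sig_cell = (
        config.cell_total_signal * (w_cell / w_cell.sum())[:, None]
        * _lognormal_noise(rng, config.noise_cv, (n, reps))
    )
    sig_sev = (
        config.sev_total_signal * (w_sev / w_sev.sum())[:, None]
        * _lognormal_noise(rng, config.noise_cv, (n, reps))
    )

    p_cell = rng.uniform(0.0, config.dabg_detected_max, size=(n, reps))
    p_sev = np.where(
        sev_detected[:, None],
        rng.uniform(0.0, config.dabg_detected_max, size=(n, reps)),
        rng.uniform(config.dabg_undetected_min, 1.0, size=(n, reps)),
    )

    cell = AbundanceProfile("CELL", ids, sig_cell, p_cell)
    sev = AbundanceProfile("SEV", ids, sig_sev, p_sev)

    # --- sequences --------------------------------------------------------
    records: dict[str, str] = {}
    for i, mid in enumerate(ids):
        length = int(rng.integers(config.seq_len_min, config.seq_len_max + 1))
        probs = _class_base_probs(classes[i], config.gc_bias)
        seq = "".join(rng.choice(list(RNA_BASES), size=length, p=probs))
        records[mid] = seq
    for consensus, rate_pos, rate_bg in config.planted_motifs:
        planted = consensus.upper().replace("T", "U")
        for i, mid in enumerate(ids):
            rate = {"SEV_ENRICHED": rate_pos, "CELL_ENRICHED": rate_bg,
                    "NEUTRAL": 0.0}[classes[i]]
            if rng.random() < rate:
                seq = records[mid]
                start = int(rng.integers(0, len(seq) - len(planted) + 1))
                records[mid] = seq[:start] + planted + seq[start + len(planted):]
    seqs = SequenceSet(records)

    # --- motif collection -------------------------------------------------
    motifs: list[MotifModel] = []
    motif_targets: dict[str, str | None] = {}
    for consensus, rate_pos, rate_bg in config.planted_motifs:
        mid = f"planted_{consensus}"
        motifs.append(
            MotifModel(mid, f"RBP_{consensus}", "Mus musculus",
                       consensus_to_pfm(consensus))
        )
        if rate_pos > rate_bg:
            motif_targets[mid] = "SEV"
        elif rate_bg > rate_pos:
            motif_targets[mid] = "CELL"
        else:
            motif_targets[mid] = None
    for m in random_decoy_motifs(config.n_decoy_motifs):
        motifs.append(m)
        motif_targets[m.motif_id] = None

    return SimulationResult(cell, sev, seqs, motifs,
                            GroundTruth(truth_class, motif_targets))


def enrichment_scenario(
    n_pos: int = 60,
    n_bg: int = 240,
    plant_rate_pos: float = 0.8,
    plant_rate_bg: float = 0.05,
    consensus: str = "AGGGA",
    n_decoy_motifs: int = 20,
    seq_len_range: tuple[int, int] = (18, 25),
    seed: int = 1,
) -> tuple[SequenceSet, SequenceSet, list[MotifModel]]:
    """Two sequence classes with one motif planted at different rates, plus
    decoys — the standalone test bed for the enrichment stage."""
    rng = np.random.default_rng(seed)
    planted = consensus.upper().replace("T", "U")

    def make(prefix: str, count: int, rate: float) -> SequenceSet:
        recs = {}
        for i in range(count):
            length = int(rng.integers(seq_len_range[0], seq_len_range[1] + 1))
            seq = "".join(rng.choice(list(RNA_BASES), size=length))
            if rng.random() < rate:
                start = int(rng.integers(0, length - len(planted) + 1))
                seq = seq[:start] + planted + seq[start + len(planted):]
            recs[f"{prefix}-{i + 1:03d}"] = seq
        return SequenceSet(recs)

    pos = make("pos", n_pos, plant_rate_pos)
    bg = make("bg", n_bg, plant_rate_bg)
    motifs = [
        MotifModel(f"planted_{planted}", f"RBP_{planted}", "Mus musculus",
                   consensus_to_pfm(planted))
    ] + random_decoy_motifs(n_decoy_motifs)
    return pos, bg, motifs


# ---------------------------------------------------------------------------
# Recovery metrics
# ---------------------------------------------------------------------------


def truth_report(
    truth: GroundTruth,
    table: LocalizationTable,
    enrich: Sequence[MotifEnrichmentResult] | None = None,
    cv: dict[str, CVReport] | None = None,
) -> dict:
    """Recovery of the planted structure by the pipeline.

    Reports per-class sensitivity/specificity of the localization calls,
    the E-value rank of each planted motif in the enrichment results, and
    each classifier's AUC against the *true* (not called) class labels.
    """
    ids = list(table.table.index)
    if set(ids) != set(truth.mirna_class):
        raise ValueError("localization table and ground truth ids differ")
    out: dict = {"classification": {}}
    calls = table.table["call"]
    for cls in ("SEV_ENRICHED", "CELL_ENRICHED"):
        true_pos = [m for m in ids if truth.mirna_class[m] == cls]
        true_neg = [m for m in ids if truth.mirna_class[m] != cls]
        sens = (
            np.mean([calls[m] == cls for m in true_pos]) if true_pos else np.nan
        )
        spec = (
            np.mean([calls[m] != cls for m in true_neg]) if true_neg else np.nan
        )
        out["classification"][cls] = {
            "sensitivity": float(sens), "specificity": float(spec),
            "n_true": len(true_pos),
        }
    if enrich is not None:
        ranked = sorted(enrich, key=lambda r: (r.e_value, r.motif_id))
        ranks = {}
        for mid, target in truth.motif_targets.items():
            if target is None:
                continue
            pos = [i for i, r in enumerate(ranked, 1) if r.motif_id == mid]
            ranks[mid] = {
                "rank": pos[0] if pos else None,
                "e_value": ranked[pos[0] - 1].e_value if pos else None,
                "target": target,
            }
        out["planted_motifs"] = ranks
    if cv is not None:
        out["auc_vs_truth"] = {}
        for model, report in cv.items():
            true_y = []
            scores = []
            for mid, p in zip(report.mirna_ids, report.probabilities):
                cls = truth.mirna_class[mid]
                if cls in ("SEV_ENRICHED", "CELL_ENRICHED"):
                    true_y.append(int(cls == "SEV_ENRICHED"))
                    scores.append(p)
            out["auc_vs_truth"][model] = (
                auc_score(true_y, scores)
                if len(set(true_y)) == 2 else float("nan")
            )
    return out
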