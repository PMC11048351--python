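"""Readers and writers for the pipeline's external representations.

Covers per-compartment miRNA abundance tables (signal + detection p-value
per replicate), miRNA sequences in FASTA, RNA-binding-protein motifs in the
CISBP-RNA text layout, YAML configuration, and the TSV result tables the
downstream stages emit.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Column order of every position-frequency matrix: A, C, G, U.
RNA_BASES = "ACGU"

COMPARTMENTS = ("CELL", "SEV")


class FormatError(ValueError):
    """A file violated the expected layout or an invariant of its contents."""


# ---------------------------------------------------------------------------
# Abundance profiles
# ---------------------------------------------------------------------------


@dataclass
class AbundanceProfile:
    """miRNA x replicate signal matrix for one compartment.

    ``signals`` holds non-negative linear-scale intensities and
    ``detection_p`` the matching detected-above-background (DABG) p-values;
    both are ``(n_mirna, n_replicates)``.
    """

    compartment: str
    mirna_ids: list[str]
    signals: np.ndarray
    detection_p: np.ndarray

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise FormatError(
                f"compartment must be one of {COMPARTMENTS}, got {self.compartment!r}"
            )
        self.mirna_ids = list(self.mirna_ids)
        self.signals = np.asarray(self.signals, dtype=float)
        self.detection_p = np.asarray(self.detection_p, dtype=float)
        n = len(self.mirna_ids)
        if self.signals.shape != self.detection_p.shape or self.signals.ndim != 2:
            raise FormatError("signals and detection_p must be equal-shape 2-D arrays")
        if self.signals.shape[0] != n:
            raise FormatError(
                f"{self.signals.shape[0]} signal rows for {n} miRNA ids"
            )
        if self.n_replicates < 2:
            raise FormatError("at least 2 replicates are required")
        if len(set(self.mirna_ids)) != n:
            raise FormatError("duplicate miRNA ids in profile")
        bad = np.argwhere(~(self.signals >= 0))
        if bad.size:
            i, j = bad[0]
            raise FormatError(
                f"negative or non-finite signal for {self.mirna_ids[i]!r} replicate {j + 1}"
            )
        bad = np.argwhere(~((self.detection_p >= 0) & (self.detection_p <= 1)))
        if bad.size:
            i, j = bad[0]
            raise FormatError(
                f"detection p outside [0,1] for {self.mirna_ids[i]!r} replicate {j + 1}"
            )

    @property
    def n_replicates(self) -> int:
        return self.signals.shape[1]

    def row(self, mirna_id: str) -> int:
        return self.mirna_ids.index(mirna_id)


def read_abundance_table(path: str | Path, compartment: str) -> AbundanceProfile:
    """Read a TSV of ``mirna_id`` plus ``signal_rep{i}`` / ``dabg_p_rep{i}`` pairs."""
    df = pd.read_csv(path, sep="\t")
    if "mirna_id" not in df.columns:
        raise FormatError(f"{path}: missing 'mirna_id' column")
    sig_cols = sorted(
        (c for c in df.columns if re.fullmatch(r"signal_rep\d+", c)),
        key=lambda c: int(c.rsplit("rep", 1)[1]),
    )
    p_cols = sorted(
        (c for c in df.columns if re.fullmatch(r"dabg_p_rep\d+", c)),
        key=lambda c: int(c.rsplit("rep", 1)[1]),
    )
    if not sig_cols or len(sig_cols) != len(p_cols):
        raise FormatError(
            f"{path}: expected matching signal_rep{{i}}/dabg_p_rep{{i}} column pairs, "
            f"found {len(sig_cols)} signal and {len(p_cols)} p columns"
        )
    try:
        return AbundanceProfile(
            compartment=compartment,
            mirna_ids=[str(x) for x in df["mirna_id"]],
            signals=df[sig_cols].to_numpy(float),
            detection_p=df[p_cols].to_numpy(float),
        )
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_abundance_table(profile: AbundanceProfile, path: str | Path) -> None:
    cols: dict[str, object] = {"mirna_id": profile.mirna_ids}
    for j in range(profile.n_replicates):
        cols[f"signal_rep{j + 1}"] = profile.signals[:, j]
    for j in range(profile.n_replicates):
        cols[f"dabg_p_rep{j + 1}"] = profile.detection_p[:, j]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------


@dataclass
class SequenceSet:
    """miRNA id -> RNA sequence, normalized to uppercase ACGU."""

    records: dict[str, str]

    def __post_init__(self) -> None:
        normalized = {}
        for name, seq in self.records.items():
            normalized[name] = normalize_rna(seq, record=name)
        self.records = normalized

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(self, ids: Iterable[str]) -> "SequenceSet":
        ids = list(ids)
        missing = [i for i in ids if i not in self.records]
        if missing:
            raise KeyError(f"sequences missing for: {missing[:5]}")
        return SequenceSet({i: self.records[i] for i in ids})


def normalize_rna(seq: str, record: str = "?") -> str:
    """Uppercase, map T->U, and reject anything outside ACGU."""
    s = str(seq).strip().upper().replace("T", "U")
    if not s:
        raise FormatError(f"record {record!r}: empty sequence")
    bad = set(s) - set(RNA_BASES)
    if bad:
        raise FormatError(
            f"record {record!r}: non-ACGT/U character(s) {sorted(bad)}"
        )
    return s


def read_fasta(path: str | Path) -> SequenceSet:
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"{path}: duplicate FASTA id {rec.id!r}")
        records[rec.id] = normalize_rna(str(rec.seq), record=rec.id)
    return SequenceSet(records)


def write_fasta(seqs: SequenceSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.records.items():
            fh.write(f">{name}\n{seq}\n")


# ---------------------------------------------------------------------------
# CISBP-RNA motifs
# ---------------------------------------------------------------------------


@dataclass
class MotifModel:
    """One RBP motif: a position frequency matrix over (A, C, G, U).

    Rows are renormalized to sum to 1 on construction; ``consensus`` is the
    most-probable base per position with alphabetical tie-break.
    """

    motif_id: str
    rbp_name: str
    species: str
    pfm: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        pfm = np.asarray(self.pfm, dtype=float)
        if pfm.ndim != 2 or pfm.shape[1] != 4:
            raise FormatError(f"motif {self.motif_id}: PFM must be (width, 4)")
        if pfm.shape[0] < 3:
            raise FormatError(f"motif {self.motif_id}: width must be >= 3")
        self.pfm = normalize_pfm(pfm, motif_id=self.motif_id)

    @property
    def width(self) -> int:
        return self.pfm.shape[0]

    @property
    def consensus(self) -> str:
        # np.argmax breaks ties by first index, i.e. alphabetically in ACGU.
        return "".join(RNA_BASES[b] for b in np.argmax(self.pfm, axis=1))


def normalize_pfm(pfm: np.ndarray, motif_id: str = "?") -> np.ndarray:
    pfm = np.asarray(pfm, dtype=float)
    if np.any(pfm < 0):
        raise FormatError(f"motif {motif_id}: negative PFM entries")
    sums = pfm.sum(axis=1)
    zero = np.nonzero(sums == 0)[0]
    if zero.size:
        raise FormatError(f"motif {motif_id}: PFM row {zero[0] + 1} sums to 0")
    return pfm / sums[:, None]


_CISBP_HEADER = re.compile(r"pos\s+a\s+c\s+g\s+[ut]\s*$", re.IGNORECASE)


def read_cisbp_pwm(path: str | Path, motif_id: str) -> np.ndarray:
    """Parse one CISBP-RNA text PWM ('Pos A C G U' header, one row per position).

    Both U and T dialects are accepted; columns are always returned in ACGU
    order.
    """
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines or not _CISBP_HEADER.match(lines[0].strip()):
        raise FormatError(f"{path}: expected 'Pos A C G U' (or T) header line")
    rows = []
    for ln in lines[1:]:
        parts = ln.split()
        if len(parts) != 5:
            raise FormatError(f"{path}: malformed PWM row {ln!r}")
        rows.append([float(x) for x in parts[1:]])
    return normalize_pfm(np.array(rows), motif_id=motif_id)


def write_cisbp_pwm(motif: MotifModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("Pos\tA\tC\tG\tU\n")
        for i, row in enumerate(motif.pfm, start=1):
            fh.write(f"{i}\t" + "\t".join(f"{x:.6f}" for x in row) + "\n")


def read_cisbp_motifs(
    pwm_dir: str | Path,
    metadata: str | Path,
    species: str | None = None,
) -> list[MotifModel]:
    """Load a CISBP-RNA-style motif collection.

    ``metadata`` is a TSV with columns Motif_ID, RBP_Name, Species; each
    Motif_ID maps to ``<pwm_dir>/<Motif_ID>.txt``. IDs whose PWM file is
    missing are skipped with a logged warning. When ``species`` is given,
    only motifs annotated to it are returned.
    """
    pwm_dir = Path(pwm_dir)
    meta = pd.read_csv(metadata, sep="\t")
    required = {"Motif_ID", "RBP_Name", "Species"}
    if not required.issubset(meta.columns):
        raise FormatError(
            f"{metadata}: metadata needs columns {sorted(required)}"
        )
    motifs: list[MotifModel] = []
    for _, row in meta.iterrows():
        if species is not None and str(row["Species"]) != species:
            continue
        pwm_path = pwm_dir / f"{row['Motif_ID']}.txt"
        if not pwm_path.exists():
            logger.warning("no PWM file for motif %s; skipped", row["Motif_ID"])
            continue
        pfm = read_cisbp_pwm(pwm_path, motif_id=str(row["Motif_ID"]))
        motifs.append(
            MotifModel(
                motif_id=str(row["Motif_ID"]),
                rbp_name=str(row["RBP_Name"]),
                species=str(row["Species"]),
                pfm=pfm,
            )
        )
    return motifs


def write_cisbp_motifs(
    motifs: Iterable[MotifModel], pwm_dir: str | Path, metadata: str | Path
) -> None:
    pwm_dir = Path(pwm_dir)
    pwm_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for m in motifs:
        write_cisbp_pwm(m, pwm_dir / f"{m.motif_id}.txt")
        rows.append({"Motif_ID": m.motif_id, "RBP_Name": m.rbp_name, "Species": m.species})
    pd.DataFrame(rows).to_csv(metadata, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------


def load_config(path: str | Path) -> Mapping:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a YAML mapping")
    return cfg
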