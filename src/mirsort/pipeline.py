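"""Orchestrate simulate -> classify -> enrich -> features -> cross-validate.

A run consumes either a simulation block (synthetic data with ground truth)
or paths to abundance tables, a FASTA file, and a CISBP-RNA motif
collection. Every artifact is a plain-text table; the run log is
deterministic (no wall-clock content) and a MANIFEST records the SHA-256 of
each artifact plus completion status, so reruns under the same config are
hash-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from . import io_formats, localization, motif_enrichment, prediction, synthetic_data
from .io_formats import FormatError, load_config

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    out_dir: Path
    simulation: synthetic_data.SimulationConfig | None = None
    cell_path: Path | None = None
    sev_path: Path | None = None
    fasta_path: Path | None = None
    pwm_dir: Path | None = None
    motif_metadata: Path | None = None
    species: str | None = None
    dabg_alpha: float = 0.05
    q: float = 0.05
    e_threshold: float = 0.05
    holdout_frac: float = 0.10
    k_folds: int = 10
    seed: int = 1
    models: Sequence[str] = prediction.MODELS

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        for name in ("dabg_alpha", "q", "e_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.simulation is None:
            missing = [
                n for n in ("cell_path", "sev_path", "fasta_path", "pwm_dir",
                            "motif_metadata")
                if getattr(self, n) is None
            ]
            if missing:
                raise ValueError(
                    f"either a simulation block or input paths are required; "
                    f"missing {missing}"
                )
            for n in ("cell_path", "sev_path", "fasta_path", "pwm_dir",
                      "motif_metadata"):
                p = Path(getattr(self, n))
                setattr(self, n, p)
                if not p.exists():
                    raise ValueError(f"{n}: {p} does not exist")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = dict(load_config(path))
        sim = raw.pop("simulation", None)
        if sim is not None:
            raw["simulation"] = synthetic_data.SimulationConfig(**sim)
        for key in ("cell_path", "sev_path", "fasta_path", "pwm_dir",
                    "motif_metadata", "out_dir"):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        if "models" in raw:
            raw["models"] = tuple(raw["models"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(out_dir: Path, status: str) -> None:
    lines = [f"status: {status}"]
    for p in sorted(out_dir.rglob("*")):
        if p.is_file() and p.name != "MANIFEST":
            lines.append(f"{p.relative_to(out_dir)}\t{_sha256(p)}")
    (out_dir / "MANIFEST").write_text("\n".join(lines) + "\n")


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all stages; returns the report directory.

    Any stage error aborts with a stage-named :class:`PipelineError`;
    partial outputs are retained and the MANIFEST marks the run incomplete.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [f"seed={config.seed}"]
    stage = "setup"
    truth = None
    try:
        # ------------------------------------------------------------ inputs
        stage = "inputs"
        if config.simulation is not None:
            sim = synthetic_data.simulate(config.simulation)
            cell, sev, seqs, motifs = sim.cell, sim.sev, sim.seqs, sim.motifs
            truth = sim.truth
            io_formats.write_abundance_table(cell, out / "cell.tsv")
            io_formats.write_abundance_table(sev, out / "sev.tsv")
            io_formats.write_fasta(seqs, out / "sequences.fa")
            io_formats.write_cisbp_motifs(motifs, out / "motifs",
                                          out / "motif_metadata.tsv")
            with open(out / "ground_truth.tsv", "w") as fh:
                fh.write("mirna_id\ttrue_class\n")
                for mid, cls in truth.mirna_class.items():
                    fh.write(f"{mid}\t{cls}\n")
            log_lines.append(
                f"stage=inputs source=simulation n_mirna={len(cell.mirna_ids)} "
                f"n_motifs={len(motifs)}"
            )
        else:
            cell = io_formats.read_abundance_table(config.cell_path, "CELL")
            sev = io_formats.read_abundance_table(config.sev_path, "SEV")
            seqs = io_formats.read_fasta(config.fasta_path)
            motifs = io_formats.read_cisbp_motifs(
                config.pwm_dir, config.motif_metadata, species=config.species
            )
            if not motifs:
                raise FormatError("motif collection is empty after filtering")
            log_lines.append(
                f"stage=inputs source=files n_mirna={len(cell.mirna_ids)} "
                f"n_motifs={len(motifs)}"
            )

        # ------------------------------------------------------ localization
        stage = "localization"
        table = localization.classify_localization(
            cell, sev, q=config.q, dabg_alpha=config.dabg_alpha
        )
        table.to_tsv(out / "localization.tsv")
        counts = table.counts
        log_lines.append(
            "stage=localization "
            + " ".join(f"{k.lower()}={v}" for k, v in counts.items())
        )

        stage = "sequence_stats"
        have_seq = [m for m in table.table.index if m in seqs.records]
        stats = localization.compare_class_sequence_stats(
            localization.LocalizationTable(table.table.loc[have_seq],
                                           table.q_threshold),
            seqs,
        )
        stats.per_class.to_csv(out / "class_sequence_stats.tsv", sep="\t",
                               index=False)
        stats.tests.to_csv(out / "class_sequence_tests.tsv", sep="\t",
                           index=False)
        log_lines.append(f"stage=sequence_stats n_with_sequence={len(have_seq)}")

        # -------------------------------------------------------- enrichment
        stage = "enrichment"
        sev_ids = [m for m in table.members("SEV_ENRICHED") if m in seqs.records]
        cell_ids = [m for m in table.members("CELL_ENRICHED") if m in seqs.records]
        if not sev_ids or not cell_ids:
            raise PipelineError(
                "enrichment: an enriched class is empty; nothing to compare"
            )
        pos_set = seqs.subset(sev_ids)
        bg_set = seqs.subset(cell_ids)
        enr_sev = motif_enrichment.sea_enrich(
            pos_set, bg_set, motifs, config.holdout_frac, seed=config.seed
        )
        enr_cell = motif_enrichment.sea_enrich(
            bg_set, pos_set, motifs, config.holdout_frac, seed=config.seed
        )
        motif_enrichment.write_enrichment_tsv(enr_sev,
                                              out / "enrichment_sev_vs_cell.tsv")
        motif_enrichment.write_enrichment_tsv(enr_cell,
                                              out / "enrichment_cell_vs_sev.tsv")
        n_sig = len(motif_enrichment.significant_motifs(enr_sev + enr_cell,
                                                        config.e_threshold))
        log_lines.append(
            f"stage=enrichment n_pos={len(sev_ids)} n_bg={len(cell_ids)} "
            f"n_significant={n_sig}"
        )

        # ---------------------------------------------------------- features
        stage = "features"
        scan_rows = [
            r for motif in motifs
            for r in motif_enrichment.scan(seqs.subset(sev_ids + cell_ids), motif)
        ]
        features = prediction.build_features(
            scan_rows, enr_sev + enr_cell, table, config.e_threshold
        )
        features.to_tsv(out / "features.tsv")
        log_lines.append(
            f"stage=features n_rows={features.X.shape[0]} "
            f"n_motif_features={features.X.shape[1]}"
        )

        # ---------------------------------------------------- cross-validation
        stage = "cross_validation"
        reports = prediction.cross_validate(
            features, k=config.k_folds, seed=config.seed, models=config.models
        )
        prediction.write_cv_reports(reports, out)
        log_lines.append(
            "stage=cross_validation "
            + " ".join(f"auc_{m}={r.auc_roc:.4f}" for m, r in reports.items())
        )

        stage = "truth_report"
        if truth is not None:
            recovery = synthetic_data.truth_report(truth, table, enr_sev, reports)
            (out / "truth_recovery.json").write_text(
                json.dumps(recovery, indent=2, sort_keys=True) + "\n"
            )

        (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
        _write_manifest(out, "complete")
        return out
    except Exception as exc:
        log_lines.append(f"stage={stage} error={exc}")
        (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
        _write_manifest(out, f"incomplete (failed at {stage})")
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"{stage}: {exc}") from exc
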