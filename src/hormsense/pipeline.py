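"""Config-driven end-to-end runner.

Chains every stage — per-contrast PLS-DA and VIP, variation factors with
Tukey-adjusted significance, the VIP/VF gate, DEG filtering, pathway TWCS,
and THSI ranking — writing one TSV per result table plus a JSON manifest
with the config echo, seed, and content hashes that make a run
reproducible and verifiable. Contrasts failing the model-validity gate are
reported in the model summary and logged as warnings but still scored.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .errors import HormsenseError
from .io_tables import (
    DEFAULT_HORMONE_PATHWAY_MAP,
    read_deg_table,
    read_hormone_table,
    read_pathway_annotation,
    read_qpcr_table,
    validate_hormone_pathway_map,
)
from .pathway import DegThresholds, compute_twcs_table
from .selection import SelectionThresholds, select_altered_hormones
from .thsi import compute_thsi, rank_hormones, summarize_tissue_contrast

logger = logging.getLogger("hormsense")

RESULT_FILES = (
    "plsda_summary.tsv",
    "vip_vf.tsv",
    "twcs.tsv",
    "thsi.tsv",
    "tissue_summary.tsv",
)


@dataclass
class PipelineConfig:
    """Inputs, thresholds, and options of a full pipeline run."""

    hormones_path: str
    degs_path: str
    annotation_path: str
    qpcr_path: str | None = None
    hormone_dialect: str = "wide"
    vip_min: float = 1.0
    vf_min: float = 25.0
    alpha: float = 0.05
    fc_low: float = 0.5
    fc_high: float = 2.0
    validity_threshold: float = 0.5
    n_components: int = 2
    w_direct: float = 1.0
    w_indirect: float = 0.5
    hormone_pathway_map: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_HORMONE_PATHWAY_MAP)
    )
    output_dir: str = "results"
    seed: int = 0

    def validate(self) -> None:
        for name in ("vip_min", "vf_min", "alpha", "validity_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.fc_low < 1 < self.fc_high:
            raise ValueError("fold-change thresholds must straddle 1 (fc_low < 1 < fc_high)")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the run manifest.

    The manifest echoes the full config, lists every result table with its
    SHA-256 content hash, and records per-stage row counts. On any stage
    failure the partially written outputs are removed and the stage's typed
    error is re-raised with the stage name attached.
    """
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "load-inputs"
    try:
        ds = read_hormone_table(config.hormones_path, config.hormone_dialect)
        degs = read_deg_table(config.degs_path)
        annotation = read_pathway_annotation(config.annotation_path)
        mapping = validate_hormone_pathway_map(
            config.hormone_pathway_map, ds.hormone_names
        )
        logger.info(
            "loaded %d hormone samples, %d DEG rows, %d annotation rows",
            len(ds.samples), len(degs), len(annotation),
        )

        stage = "plsda-selection"
        thresholds = SelectionThresholds(
            vip_min=config.vip_min, vf_min=config.vf_min, alpha=config.alpha
        )
        records, model_summary = select_altered_hormones(
            ds,
            n_components=config.n_components,
            thresholds=thresholds,
            validity_threshold=config.validity_threshold,
        )
        for _, row in model_summary[~model_summary["valid"]].iterrows():
            logger.warning(
                "PLS-DA model for tissue=%s dose=%g fails the validity gate "
                "(r2x=%.3f r2y=%.3f q2=%.3f); scoring anyway",
                row["tissue"], row["dose_mg_L"], row["r2x"], row["r2y"], row["q2"],
            )
        logger.info("selection: %d hormone/contrast records", len(records))

        stage = "pathway-twcs"
        twcs = compute_twcs_table(
            degs,
            annotation,
            DegThresholds(low=config.fc_low, high=config.fc_high, alpha=config.alpha),
            w_direct=config.w_direct,
            w_indirect=config.w_indirect,
        )
        logger.info("twcs: %d pathway/contrast records", len(twcs))

        stage = "thsi"
        thsi = rank_hormones(compute_thsi(records, twcs, mapping))
        summary = summarize_tissue_contrast(thsi)
        logger.info("thsi: %d records", len(thsi))

        stage = "qpcr-concordance"
        qpcr = read_qpcr_table(config.qpcr_path) if config.qpcr_path else None

        stage = "write-outputs"
        tables: dict[str, pd.DataFrame] = {
            "plsda_summary.tsv": model_summary,
            "vip_vf.tsv": records,
            "twcs.tsv": twcs,
            "thsi.tsv": thsi,
            "tissue_summary.tsv": summary,
        }
        if qpcr is not None:
            tables["qpcr.tsv"] = qpcr
        for name, frame in tables.items():
            path = out_dir / name
            frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
            written.append(path)

        manifest = {
            "config": asdict(config),
            "seed": config.seed,
            "tables": {p.name: _sha256(p) for p in written},
            "row_counts": {name: len(frame) for name, frame in tables.items()},
            "invalid_contrasts": int((~model_summary["valid"]).sum()),
        }
        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        manifest["manifest_path"] = str(manifest_path)
        return manifest
    except HormsenseError as err:
        for p in written:
            p.unlink(missing_ok=True)
        raise type(err)(f"[stage: {stage}] {err}") from err
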