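"""Synthetic hormone datasets and annotated DEG tables with known planted
effects, emulating a two-tissue, dose-response hydroponic stress study:
2 tissues × 4 dose levels (a control plus low/medium/high stressor
concentrations) × 3 biological replicates, with a 17-hormone targeted panel.

Concentration noise is lognormal (concentrations are positive, ng/g fresh
weight) parameterized by a coefficient of variation; a planted effect sets
the treated-group mean to control_mean × (1 + VF/100). DEG fold changes and
p-values are generated coherently from a two-sample t model on simulated
log2 expression replicates, so a strongly planted gene gets both a large
fold change and a small p-value.

Every generator also emits a :class:`GroundTruth` record so recovery tests
check against the planted design instead of reverse-engineering the
generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .io_tables import (
    DEFAULT_HORMONE_PATHWAY_MAP,
    DEFAULT_HORMONES,
    DegTable,
    HormoneDataset,
    PathwayAnnotation,
    TISSUES,
)

#: Study dose levels in mg SCN−/L: control, low, medium, high.
DEFAULT_DOSES = (0.0, 4.80, 20.0, 124.0)

_SD_WITHIN_LOG2 = 0.25  # within-group SD of log2 expression replicates


@dataclass
class SynthConfig:
    """Parameters of the synthetic study.

    planted_effects maps (hormone, tissue, dose) to a target VF in percent;
    planted_log2fc maps (pathway, tissue, dose) to (mean, sd) of the true
    log2 fold change of that pathway's genes. Contrasts absent from either
    mapping are generated as pure noise.
    """

    tissues: tuple[str, ...] = TISSUES
    doses: tuple[float, ...] = DEFAULT_DOSES
    replicates: int = 3
    hormones: tuple[str, ...] = DEFAULT_HORMONES
    baseline_mean: float = 50.0  # ng/g FW, geometric center of per-hormone baselines
    cv: float = 0.15  # replicate-level coefficient of variation
    planted_effects: dict[tuple[str, str, float], float] = field(default_factory=dict)
    genes_per_pathway: tuple[int, int] = (6, 8)  # (direct, indirect)
    planted_log2fc: dict[tuple[str, str, float], tuple[float, float]] = field(
        default_factory=dict
    )
    null_gene_count: int = 400
    seed: int = 0

    def validate(self) -> None:
        if 0.0 not in self.doses:
            raise ConfigError("doses must include the 0 control")
        if self.replicates < 2:
            raise ConfigError("need at least 2 replicates per group")
        if self.cv <= 0:
            raise ConfigError("cv must be positive")
        if self.baseline_mean <= 0:
            raise ConfigError("baseline_mean must be positive")
        if any(c < 0 for c in self.genes_per_pathway) or self.null_gene_count < 0:
            raise ConfigError("gene counts must be non-negative")
        if len(set(self.hormones)) != len(self.hormones):
            raise ConfigError("hormone names must be unique")
        for (h, t, d), vf in self.planted_effects.items():
            if h not in self.hormones or t not in self.tissues or d not in self.doses:
                raise ConfigError(f"planted effect refers to unknown design cell {(h, t, d)}")
            if vf <= -100:
                raise ConfigError("a VF of -100% or lower gives a non-positive mean")

    @property
    def treatment_doses(self) -> tuple[float, ...]:
        return tuple(d for d in self.doses if d > 0)


@dataclass
class GroundTruth:
    """Planted design, for recovery tests.

    expected_alteration applies the ±25% VF gate to the planted effects;
    expected_twcs_sign is the sign of the planted mean log2 fold change;
    intended_hub names, per (tissue, dose), the hormone the planted design
    makes most sensitive (None when nothing is planted).
    """

    true_vf: dict[tuple[str, str, float], float]
    expected_alteration: dict[tuple[str, str, float], str]
    expected_twcs_sign: dict[tuple[str, str, float], int]
    intended_hub: dict[tuple[str, float], str | None]


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given arithmetic mean and CV."""
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def _expected_twcs(cfg: SynthConfig, pathway: str, tissue: str, dose: float) -> float:
    planted = cfg.planted_log2fc.get((pathway, tissue, dose))
    if planted is None:
        return 0.0
    mean, _ = planted
    n_direct, m_indirect = cfg.genes_per_pathway
    score = 0.0
    if n_direct:
        score += mean * 1.0
    if m_indirect:
        score += mean * 0.5
    return score


def _build_ground_truth(cfg: SynthConfig, vf_gate: float = 25.0) -> GroundTruth:
    pathway_of = DEFAULT_HORMONE_PATHWAY_MAP
    true_vf: dict[tuple[str, str, float], float] = {}
    expected_alt: dict[tuple[str, str, float], str] = {}
    for tissue in cfg.tissues:
        for dose in cfg.treatment_doses:
            for h in cfg.hormones:
                vf = cfg.planted_effects.get((h, tissue, dose), 0.0)
                true_vf[(h, tissue, dose)] = vf
                if vf > vf_gate:
                    expected_alt[(h, tissue, dose)] = "positive"
                elif vf < -vf_gate:
                    expected_alt[(h, tissue, dose)] = "negative"
                else:
                    expected_alt[(h, tissue, dose)] = "none"
    twcs_sign = {
        (pw, t, d): int(np.sign(_expected_twcs(cfg, pw, t, d)))
        for pw in sorted(set(pathway_of.values()))
        for t in cfg.tissues
        for d in cfg.treatment_doses
    }
    hub: dict[tuple[str, float], str | None] = {}
    for tissue in cfg.tissues:
        for dose in cfg.treatment_doses:
            best, best_score = None, 0.0
            for h in cfg.hormones:
                if expected_alt[(h, tissue, dose)] == "none":
                    continue
                pw = pathway_of.get(h)
                if pw is None:
                    continue
                score = abs(true_vf[(h, tissue, dose)]) / 100.0 * abs(
                    _expected_twcs(cfg, pw, tissue, dose)
                )
                if score > best_score:
                    best, best_score = h, score
            hub[(tissue, dose)] = best
    return GroundTruth(
        true_vf=true_vf,
        expected_alteration=expected_alt,
        expected_twcs_sign=twcs_sign,
        intended_hub=hub,
    )


def generate_hormone_dataset(cfg: SynthConfig) -> tuple[HormoneDataset, GroundTruth]:
    """Draw a replicate-level hormone concentration table from the config.

    Per-hormone baselines are spread lognormally (CV 0.8) around
    ``baseline_mean`` so the panel spans a realistic concentration range;
    replicate noise is lognormal at the configured CV. The same seed always
    yields the same dataset.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    mu_b, sd_b = _lognormal_params(cfg.baseline_mean, 0.8)
    baselines = {
        (h, t): float(rng.lognormal(mu_b, sd_b))
        for t in cfg.tissues
        for h in cfg.hormones
    }
    rows = []
    conc = []
    for tissue in cfg.tissues:
        for dose in cfg.doses:
            for rep in range(1, cfg.replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{tissue}_d{dose:g}_r{rep}",
                        "tissue": tissue,
                        "dose_mg_L": float(dose),
                        "replicate": rep,
                    }
                )
                sample = []
                for h in cfg.hormones:
                    mean = baselines[(h, tissue)]
                    if dose > 0:
                        vf = cfg.planted_effects.get((h, tissue, dose), 0.0)
                        mean *= 1.0 + vf / 100.0
                    mu, sd = _lognormal_params(mean, cfg.cv)
                    sample.append(rng.lognormal(mu, sd))
                conc.append(sample)
    ds = HormoneDataset(
        samples=pd.DataFrame(rows),
        concentrations=np.array(conc),
        hormone_names=list(cfg.hormones),
    )
    return ds, _build_ground_truth(cfg)


def generate_deg_table(
    cfg: SynthConfig,
) -> tuple[DegTable, PathwayAnnotation, GroundTruth]:
    """Generate an annotated DEG table with coherent fold changes and p-values.

    Pathway genes (direct and indirect per ``genes_per_pathway``) get a true
    log2 fold change drawn from the planted (mean, sd) for contrasts present
    in ``planted_log2fc`` and 0 elsewhere; null genes are never differential.
    Observed fold change and p-value come from a two-sample t-test on
    simulated log2 expression replicates, keeping the two coherent.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 1)
    pathways = sorted(set(DEFAULT_HORMONE_PATHWAY_MAP.values()))
    n_direct, m_indirect = cfg.genes_per_pathway

    ann_rows = []
    gene_pathway: list[tuple[str, str | None]] = []
    for pw in pathways:
        for i in range(n_direct):
            gid = f"{pw}_direct_{i + 1:03d}"
            ann_rows.append({"gene_id": gid, "pathway": pw, "effect_class": "direct"})
            gene_pathway.append((gid, pw))
        for i in range(m_indirect):
            gid = f"{pw}_indirect_{i + 1:03d}"
            ann_rows.append({"gene_id": gid, "pathway": pw, "effect_class": "indirect"})
            gene_pathway.append((gid, pw))
    for i in range(cfg.null_gene_count):
        gene_pathway.append((f"null_{i + 1:05d}", None))

    frames = []
    nrep = cfg.replicates
    gene_ids = [gid for gid, _ in gene_pathway]
    n_genes = len(gene_ids)
    for tissue in cfg.tissues:
        for dose in cfg.treatment_doses:
            true_lfc = np.zeros(n_genes)
            for g, (gid, pw) in enumerate(gene_pathway):
                if pw is not None and (pw, tissue, dose) in cfg.planted_log2fc:
                    mean, sd = cfg.planted_log2fc[(pw, tissue, dose)]
                    true_lfc[g] = rng.normal(mean, sd)
            if n_genes == 0:
                continue
            ctrl = rng.normal(0.0, _SD_WITHIN_LOG2, (n_genes, nrep))
            treat = true_lfc[:, None] + rng.normal(0.0, _SD_WITHIN_LOG2, (n_genes, nrep))
            obs_lfc = treat.mean(axis=1) - ctrl.mean(axis=1)
            p = stats.ttest_ind(treat, ctrl, axis=1).pvalue
            frames.append(
                pd.DataFrame(
                    {
                        "gene_id": gene_ids,
                        "tissue": tissue,
                        "dose_mg_L": float(dose),
                        "fold_change": 2.0**obs_lfc,
                        "p_value": p,
                    }
                )
            )
    if frames:
        degs = DegTable(rows=pd.concat(frames, ignore_index=True))
    else:
        degs = DegTable(rows=pd.DataFrame(columns=DegTable.COLUMNS))
    annotation = PathwayAnnotation(
        rows=pd.DataFrame(ann_rows, columns=PathwayAnnotation.COLUMNS)
    )
    return degs, annotation, _build_ground_truth(cfg)


def make_paper_template_config(seed: int = 0) -> SynthConfig:
    """The default study template: 2 tissues × 4 doses × 3 replicates × 17
    hormones, with planted effects reproducing the qualitative response
    pattern of a thiocyanate-stressed rice seedling study — jasmonates and
    the ethylene precursor up-regulated (strongest in shoots), gibberellins
    suppressed, and a distinct hub hormone per tissue and dose.
    """
    d_low, d_med, d_high = 4.80, 20.0, 124.0
    planted_effects = {
        # roots: JA hub at low dose; GA3 at medium; SA at high
        ("JA", "root", d_low): 60.0,
        ("ACC", "root", d_low): 45.0,
        ("IAA", "root", d_low): 35.0,
        ("cZ", "root", d_low): 32.0,
        ("GA4", "root", d_low): -40.0,
        ("GA3", "root", d_med): 65.0,
        ("JA", "root", d_med): 40.0,
        ("GA4", "root", d_med): -35.0,
        ("SA", "root", d_high): 70.0,
        ("JA", "root", d_high): 45.0,
        ("GA4", "root", d_high): -45.0,
        ("GA7", "root", d_high): -35.0,
        # shoots: stronger responses overall; JA-Ile hub at low and high doses
        ("JA-Ile", "shoot", d_low): 85.0,
        ("JA", "shoot", d_low): 65.0,
        ("OPDA", "shoot", d_low): -45.0,
        ("GA4", "shoot", d_low): -50.0,
        ("ACC", "shoot", d_med): 80.0,
        ("JA", "shoot", d_med): 50.0,
        ("GA4", "shoot", d_med): -40.0,
        ("JA-Ile", "shoot", d_high): 90.0,
        ("ACC", "shoot", d_high): 60.0,
        ("GA4", "shoot", d_high): -55.0,
        ("GA7", "shoot", d_high): -40.0,
    }
    planted_log2fc = {
        # pathway-level transcriptional effects matching the hormone pattern
        ("JA", "root", d_low): (2.0, 0.4),
        ("ET", "root", d_low): (1.2, 0.4),
        ("GA", "root", d_low): (-1.0, 0.4),
        ("GA", "root", d_med): (1.8, 0.4),
        ("JA", "root", d_med): (1.0, 0.4),
        ("SA", "root", d_high): (2.2, 0.4),
        ("JA", "root", d_high): (1.0, 0.4),
        ("GA", "root", d_high): (-1.4, 0.4),
        ("JA", "shoot", d_low): (2.6, 0.4),
        ("GA", "shoot", d_low): (-1.4, 0.4),
        ("ET", "shoot", d_med): (2.6, 0.4),
        ("JA", "shoot", d_med): (1.2, 0.4),
        ("JA", "shoot", d_high): (2.8, 0.4),
        ("ET", "shoot", d_high): (1.6, 0.4),
        ("GA", "shoot", d_high): (-1.6, 0.4),
    }
    return SynthConfig(
        planted_effects=planted_effects,
        planted_log2fc=planted_log2fc,
        seed=seed,
    )


def config_with_seed(cfg: SynthConfig, seed: int) -> SynthConfig:
    """A copy of the config with a different seed."""
    return replace(cfg, seed=seed)
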