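"""Total Hormonal Sensitivity Index (THSI): ranking hormones by combined
concentration-level and transcript-level stress response.

For each hormone in a (tissue, dose-vs-control) contrast:

    THSI = vip_m × TWCS(pathway of the hormone)

where vip_m is the signed, gated variable importance from the VIP/VF
integration and TWCS is the weighted DEG contribution score of the hormone's
biosynthetic pathway. Hormones sharing a pathway share the TWCS factor; a
pathway with no differential genes contributes TWCS = 0, so its hormones get
THSI = 0 rather than being dropped. Hormones are ranked within each contrast
by |THSI| (sign retained for direction), ties broken by name; the rank-1
hormone is the contrast's hub.
"""

from __future__ import annotations

import pandas as pd

from .errors import MappingError
from .io_tables import validate_hormone_pathway_map


def compute_thsi(
    selection_records: pd.DataFrame,
    twcs_table: pd.DataFrame,
    hormone_pathway_map: dict[str, str],
) -> pd.DataFrame:
    """Join selection records with pathway scores and multiply.

    ``selection_records`` needs columns hormone/tissue/dose_mg_L/vip_m;
    ``twcs_table`` needs pathway/tissue/dose_mg_L/twcs. A hormone whose
    pathway has no TWCS row for the contrast receives twcs = 0.
    """
    hormones = sorted(set(selection_records["hormone"]))
    missing = [h for h in hormones if h not in hormone_pathway_map]
    if missing:
        raise MappingError(f"hormone(s) missing from the pathway map: {missing}")
    mapping = validate_hormone_pathway_map(hormone_pathway_map, hormones)

    twcs_lookup = {
        (r["pathway"], r["tissue"], float(r["dose_mg_L"])): float(r["twcs"])
        for _, r in twcs_table.iterrows()
    }
    out = selection_records.copy()
    out["pathway"] = out["hormone"].map(mapping)
    out["twcs"] = [
        twcs_lookup.get((pw, ti, float(do)), 0.0)
        for pw, ti, do in zip(out["pathway"], out["tissue"], out["dose_mg_L"])
    ]
    out["thsi"] = out["vip_m"] * out["twcs"]
    return out


def rank_hormones(thsi_records: pd.DataFrame) -> pd.DataFrame:
    """Rank hormones by descending |THSI| within each (tissue, dose).

    Ties break lexicographically by hormone name; the rank-1 hormone is
    flagged as hub. When every THSI in a contrast is zero the ranking is
    purely name-order and the hub flag is marked degenerate.
    """
    out = thsi_records.copy()
    out["abs_thsi"] = out["thsi"].abs()
    ranked = []
    for (tissue, dose), grp in out.groupby(["tissue", "dose_mg_L"], sort=True):
        grp = grp.sort_values(
            ["abs_thsi", "hormone"], ascending=[False, True], kind="mergesort"
        ).copy()
        grp["rank"] = range(1, len(grp) + 1)
        degenerate = bool((grp["abs_thsi"] == 0).all())
        grp["is_hub"] = [r == 1 and not degenerate for r in grp["rank"]]
        grp["hub_degenerate"] = degenerate
        ranked.append(grp)
    res = pd.concat(ranked, ignore_index=True).drop(columns=["abs_thsi"])
    return res


def summarize_tissue_contrast(thsi_records: pd.DataFrame) -> pd.DataFrame:
    """Mean |THSI| per tissue per dose, with the shoot:root ratio per dose.

    If one tissue is absent the summary is emitted for the present tissue
    with the ratio left missing and a ``partial`` flag set.
    """
    agg = (
        thsi_records.assign(abs_thsi=thsi_records["thsi"].abs())
        .groupby(["tissue", "dose_mg_L"])["abs_thsi"]
        .mean()
        .reset_index()
        .rename(columns={"abs_thsi": "mean_abs_thsi"})
    )
    tissues = set(agg["tissue"])
    rows = []
    for dose in sorted(set(agg["dose_mg_L"])):
        sub = agg[agg["dose_mg_L"] == dose].set_index("tissue")["mean_abs_thsi"]
        shoot = float(sub.get("shoot", float("nan")))
        root = float(sub.get("root", float("nan")))
        partial = not {"root", "shoot"} <= tissues
        ratio = shoot / root if (not partial and root != 0) else float("nan")
        rows.append(
            {
                "dose_mg_L": dose,
                "mean_abs_thsi_root": root,
                "mean_abs_thsi_shoot": shoot,
                "shoot_root_ratio": ratio,
                "partial": partial,
            }
        )
    return pd.DataFrame(rows)
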