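"""Pipeline orchestration: sequence the analysis stages over a manifest.

A manifest maps stage inputs to file paths (plus a ``params`` block for
scalars like the administered activity).  Only the stages whose inputs
are present run; each stage writes its own outputs under the results
directory and contributes to a machine-readable JSON summary.  A stage
failure is recorded and the remaining stages still run, so partial
results are retained.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import binding_assays as ba
from . import biodistribution as bd
from . import dosimetry as dm
from . import imaging_spatial as sp
from . import therapy_outcomes as to
from .core_io import StudyConfig, read_image, read_table


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    return obj


def _stage_binding(manifest, params, config, out_dir):
    result = {}
    if "lindmo" in manifest:
        assay = ba.SerialDilutionAssay.from_table(
            read_table(manifest["lindmo"], "lindmo"))
        result["lindmo"] = asdict(ba.fit_lindmo(assay))
    if "competition" in manifest:
        assay = ba.CompetitionAssay.from_table(
            read_table(manifest["competition"], "competition"))
        result["ic50"] = asdict(
            ba.fit_ic50(assay, normalize_at=params.get("normalize_at_nM", 0.03)))
    return result


def _stage_biodist(manifest, params, config, out_dir):
    table = read_table(manifest["biodist"], "biodist").data
    nuclides, _ = bd.load_nuclide_table(config.nuclide_table_path)
    nuclide = nuclides[params.get("biodist_nuclide", "In-111")]
    standard_cpm = float(params["standard_cpm"])
    standard_fraction = float(params.get("standard_fraction", 1.0))
    rows = []
    for _, row in table.iterrows():
        sample = bd.BiodistSample(organ=row["organ"], mass_g=row["mass_g"],
                                  cpm=row["cpm"], dt_days=row["dt_days"],
                                  group=row["group"], animal=row["animal"])
        rows.append({"animal": row["animal"], "group": row["group"],
                     "organ": row["organ"],
                     "pct_ia_per_g": bd.percent_ia_per_gram(
                         sample, standard_cpm, nuclide, standard_fraction)})
    values = pd.DataFrame(rows)
    values.to_csv(out_dir / "biodist_pct_ia_per_g.csv", index=False)
    result = {"per_sample": values}
    groups = sorted(values["group"].unique())
    if len(groups) == 2:
        stats_df = bd.compare_groups(values, groups[0], groups[1])
        stats_df.to_csv(out_dir / "biodist_group_stats.csv", index=False)
        result["group_stats"] = stats_df
    return result


def _stage_dosimetry(manifest, params, config, out_dir):
    table = read_table(manifest["tac"], "tac").data
    nuclides, chains = bd.load_nuclide_table(config.nuclide_table_path)
    surrogate = nuclides[params.get("tac_nuclide", "In-111")]
    target_name = params.get("therapy_nuclide", "Ac-225")
    chain = chains[target_name]
    administered = float(params.get("administered_kbq", 15.0))
    result = {}
    for voi, sub in table.groupby("voi", sort=True):
        sub = sub.sort_values("day")
        tac = dm.TimeActivityCurve(voi=voi,
                                   times_days=sub["day"].to_numpy(),
                                   pct_ia_per_ml=sub["pct_ia_per_ml"].to_numpy(),
                                   nuclide=surrogate)
        translated = dm.translate_surrogate(tac, nuclides[target_name])
        integral, tail_fraction = dm.integrate_tac(
            translated,
            rise_model=params.get("rise_model", "linear"),
            tail_model=params.get("tail_model", "phys"))
        coeff = dm.dose_coefficient(integral, chain, config.density)
        est = dm.total_dose(coeff, administered, voi=voi,
                            tail_fraction=tail_fraction)
        result[voi] = asdict(est)
    (out_dir / "dose.json").write_text(
        json.dumps(_jsonable(result), indent=2, sort_keys=True))
    return result


def _stage_spatial(manifest, params, config, out_dir):
    autorad = read_image(manifest["autorad"])
    fluor = read_image(manifest["fluor"])
    pair = sp.register_pair(autorad, fluor)
    res = sp.block_correlation(pair, block_size=config.block_size,
                               coefficient=params.get("coefficient", "pearson"))
    tiles = pd.DataFrame({"autorad_mean": res.block_means_autorad,
                          "fluor_mean": res.block_means_fluor})
    tiles.to_csv(out_dir / "spatial_tiles.csv", index=False)
    return {"r": res.r, "n_blocks": res.n_blocks,
            "block_size": res.block_size, "n_excluded": res.n_excluded,
            "coefficient": res.coefficient}


def _stage_histo(manifest, params, config, out_dir):
    table = read_table(manifest["cd45"], "cd45_snapshots").data
    summary = sp.summarize_cd45(table,
                                min_snapshots=params.get("min_snapshots", 10))
    summary["mouse_means"].to_csv(out_dir / "cd45_mouse_means.csv", index=False)
    return {k: v for k, v in summary.items() if k != "mouse_means"}


def _stage_therapy(manifest, params, config, out_dir):
    result = {}
    if "growth" in manifest:
        table = read_table(manifest["growth"], "growth").data
        fits, aucs = [], []
        for (mouse, group), sub in table.groupby(["mouse", "group"], sort=True):
            curve = to.GrowthCurve(mouse=mouse, group=group,
                                   days=sub["day"].to_numpy(),
                                   volumes_mm3=sub["volume_mm3"].to_numpy())
            curve = to.normalize_growth(curve)
            fits.append(asdict(to.fit_growth(curve, config)))
            aucs.append({"mouse": mouse, "group": group,
                         "auc_pct_days": to.growth_auc(curve)})
        fit_df = pd.DataFrame(fits)
        fit_df.to_csv(out_dir / "growth_fits.csv", index=False)
        excluded = fit_df[~fit_df["included"]]
        result["growth"] = {
            "fits": fits, "auc": aucs,
            "n_excluded": int(len(excluded)),
            # excluding plateaued curves removes best responders; surface it
            "exclusion_bias_note": (
                "curves excluded for plateauing below the endpoint threshold "
                "are the best responders; group comparisons of time-to-"
                "endpoint are biased accordingly"
            ) if (excluded["exclusion_reason"] == "plateau_below_sixfold").any()
            else None,
        }
    if "survival" in manifest:
        table = read_table(manifest["survival"], "survival").data
        groups = sorted(table["group"].unique())
        km = {g: to.km_estimate(table, g) for g in groups}
        comparisons = params.get("survival_comparisons")
        if comparisons is None:
            comparisons = [(groups[i], groups[j])
                           for i in range(len(groups))
                           for j in range(i + 1, len(groups))]
        else:
            comparisons = [tuple(c) for c in comparisons]
        logrank = to.pairwise_logrank(table, comparisons, alpha=config.alpha)
        logrank.to_csv(out_dir / "logrank.csv", index=False)
        result["survival"] = {
            "median_days": {g: km[g]["median_days"] for g in groups},
            "events": {g: km[g]["events"] for g in groups},
            "logrank": logrank,
        }
    return result


_STAGES = (
    ("binding", ("lindmo", "competition"), _stage_binding),
    ("biodist", ("biodist",), _stage_biodist),
    ("dosimetry", ("tac",), _stage_dosimetry),
    ("spatial", ("autorad", "fluor"), _stage_spatial),
    ("histo", ("cd45",), _stage_histo),
    ("therapy", ("growth", "survival"), _stage_therapy),
)


def run_pipeline(config: StudyConfig, manifest: dict, out_dir: str | Path
                 ) -> tuple[dict, dict]:
    """Run every stage whose manifest inputs are present.

    Returns ``(summary, failures)``; the summary is also written to
    ``summary.json`` (sorted keys, so identical inputs and config give
    byte-identical output).  A human-readable ``report.txt`` sits next
    to it.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params = manifest.get("params", {})
    summary: dict = {"config": {"seed": config.seed,
                                "block_size": config.block_size,
                                "sixfold_threshold": config.sixfold_threshold,
                                "r2_min": config.r2_min,
                                "hep_volume": config.hep_volume,
                                "alpha": config.alpha,
                                "density": config.density}}
    failures: dict = {}
    for name, keys, fn in _STAGES:
        if not any(k in manifest for k in keys):
            continue
        try:
            summary[name] = fn(manifest, params, config, out_dir)
        except Exception as exc:  # noqa: BLE001 - keep partial results
            failures[name] = f"{type(exc).__name__}: {exc}"
    summary["failures"] = failures
    payload = json.dumps(_jsonable(summary), indent=2, sort_keys=True)
    (out_dir / "summary.json").write_text(payload)
    lines = [f"tatkit pipeline summary (seed={config.seed})"]
    for name, *_ in _STAGES:
        status = ("FAILED: " + failures[name]) if name in failures else (
            "ok" if name in summary else "skipped (no inputs)")
        lines.append(f"  {name}: {status}")
    (out_dir / "report.txt").write_text("\n".join(lines) + "\n")
    return summary, failures


__all__ = ["run_pipeline"]
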