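"""End-to-end orchestration: simulate -> laterality -> graph -> peaks ->
extent -> resting connectivity, collected into a single reproducible report.

All randomness flows from one config seed through per-stage derived seeds,
so identical configs produce byte-identical JSON reports.  Generator truth
tables are never read by any analysis stage; the report joins estimates to
truth only inside its clearly labelled ``evaluation`` section.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import graph as pg
from . import laterality as lat
from . import peaks as pk
from . import restconn as rc
from . import stats as st
from . import synthetic as syn

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Settings for a full synthetic-cohort pipeline run."""

    seed: int = 0
    n_subjects: int = 63
    proportions: tuple[float, float, float] = (0.83, 0.09, 0.08)
    extent_kappa: float = 1.5
    noise_sd: float = 1.0
    top_fraction: float = lat.TOP_FRACTION
    threshold_fraction: float = lat.THRESHOLD_FRACTION
    bilateral_band: float = lat.BILATERAL_BAND
    threshold_source: str = "max"
    graph_resolution: float = 1.0
    negative_edge_rule: str = "truncate"
    n_rest_per_group: int = 3
    rest_volumes: int = 120
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 < self.top_fraction < 1 or not 0 < self.threshold_fraction < 1:
            raise ValueError("fractions must lie in (0, 1)")
        if not 0 < self.bilateral_band < 100:
            raise ValueError("bilateral band must lie in (0, 100)")


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s % (2 ** 31 - 1)) for s in state]


def _round(x, nd=6):
    return float(np.round(float(x), nd))


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute every stage on a simulated cohort and return the run report.

    The report carries, next to every statistic, the exact settings that
    produced it.  With ``out_dir`` the report (JSON and Markdown) and the
    stage tables (TSV/CSV/JSON) are written to disk.
    """
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))
    seeds = _stage_seeds(config.seed)
    report: dict = {"settings": asdict(config), "warnings": []}

    # --- stage 1: simulate -------------------------------------------------
    spec = syn.CohortSpec(
        n_subjects=config.n_subjects,
        proportions=config.proportions,
        extent_kappa=config.extent_kappa,
        noise_sd=config.noise_sd,
        seed=seeds[0],
    )
    maps, metas, truth = syn.simulate_cohort(spec)
    rois = syn.make_roi_pair(spec.shape)
    hemis = syn.make_cortex_masks(spec.shape)
    logger.info("simulated %d subjects on grid %s", len(maps), spec.shape)

    # --- stage 2: laterality table ----------------------------------------
    li_kwargs = dict(top_fraction=config.top_fraction,
                     threshold_fraction=config.threshold_fraction,
                     source=config.threshold_source)
    table = lat.cohort_laterality_table(maps, rois, metas,
                                        band=config.bilateral_band, **li_kwargs)
    counts = table["label"].value_counts().to_dict()
    report["laterality"] = {
        "settings": {**li_kwargs, "band": config.bilateral_band},
        "n_subjects": int(len(table)),
        "class_counts": {k: int(counts.get(k, 0)) for k in lat.LABELS},
        "table": table.round(4).to_dict(orient="records"),
    }

    # Welch on LI: right- vs left-handers among left_typical subjects
    typ = table[table["label"] == "left_typical"]
    rh = typ[typ["handedness"] == "right"]["li"].to_numpy()
    lh = typ[typ["handedness"] == "left"]["li"].to_numpy()
    if len(rh) >= 2 and len(lh) >= 2:
        w = st.welch_t_from_samples(rh, lh)
        report["handedness_welch"] = {
            "groups": "typical right-handers vs typical left-handers (lh - rh)",
            **{k: _round(v) for k, v in w.as_record().items() if k != "test"},
        }
    else:
        report["warnings"].append("handedness comparison skipped: too few typical "
                                  "right- or left-handers")

    # --- stage 3: pattern graph -------------------------------------------
    union_mask = pg.RoiMask(data=rois.left.data | rois.right.data,
                            side="none", label="broca_union")
    if config.n_subjects < 3:
        report["graph"] = {"warning": "too few subjects for communities"}
        report["warnings"].append("graph stage: too few subjects for communities")
        partition = None
    else:
        matrix = pg.similarity_matrix(maps, union_mask)
        g = pg.build_graph(matrix, negative=config.negative_edge_rule)
        partition = pg.detect_communities(g, resolution=config.graph_resolution,
                                          seed=seeds[1])
        reference = {row["subject_id"]: (0 if row["label"] == "left_typical" else 1)
                     for row in report["laterality"]["table"]}
        agreement = pg.partition_agreement(partition, reference)
        report["graph"] = {
            "settings": {"resolution": config.graph_resolution,
                         "negative_edge_rule": config.negative_edge_rule,
                         "mask": union_mask.label},
            "n_communities": partition.n_communities,
            "modularity_q": _round(partition.q),
            "agreement_with_li_labels": _round(agreement),
            "partition": partition.labels,
        }

    # --- stage 4: peaks ----------------------------------------------------
    peaks = [pk.find_peak(m, union_mask) for m in maps]
    peak_rows = pk.peaks_table(peaks).round(4).to_dict(orient="records")
    labels = table["label"].tolist()
    typical_peaks = [p for p, lab in zip(peaks, labels) if lab == "left_typical"]
    atypical_peaks = [p for p, lab in zip(peaks, labels) if lab != "left_typical"]
    expected = ["left"] * len(typical_peaks) + ["right"] * len(atypical_peaks)
    discord = pk.flag_discordant_peaks(typical_peaks + atypical_peaks, expected)
    kept_typ = [p for p, d in zip(typical_peaks, discord[: len(typical_peaks)]) if not d]
    kept_atyp = [p for p, d in zip(atypical_peaks, discord[len(typical_peaks):]) if not d]
    report["peaks"] = {"table": peak_rows,
                       "n_excluded_discordant": int(sum(discord))}
    if len(kept_typ) >= 2 and len(kept_atyp) >= 2:
        for axis in ("y", "z"):
            w = pk.compare_peak_axis(kept_typ, kept_atyp, axis)
            report["peaks"][f"welch_{axis}_axis"] = {
                "groups": "typical vs atypical (atypical - typical)",
                **{k: _round(v) for k, v in w.as_record().items() if k != "test"},
            }
    else:
        report["warnings"].append("peak axis comparison skipped: too few subjects "
                                  "in one of the groups")

    # --- stage 5: extent vs |LI| -------------------------------------------
    extents = [lat.hemispheric_extent(m, hemis, **li_kwargs) for m in maps]
    totals = [e[2] for e in extents]
    abs_li = table["li"].abs().to_numpy()
    if len(maps) >= 3:
        corr = st.pearson_with_df(abs_li, np.asarray(totals, dtype=float))
        report["extent"] = {
            "description": "Pearson correlation between |LI| and total "
                           "hemispheric suprathreshold extent",
            "r": _round(corr.r), "df": corr.df, "p": _round(corr.p),
            "totals": [int(t) for t in totals],
        }
    else:
        report["warnings"].append("extent correlation skipped: n < 3")

    # --- stage 6: resting connectivity --------------------------------------
    if config.n_rest_per_group >= 2:
        rest_spec = syn.RestingSpec(n_volumes=config.rest_volumes)
        rng = np.random.default_rng(seeds[2])
        analysis_seeds = [rc.SeedSpec(center_mm=p.center_mm, name=p.name)
                          for p in rest_spec.seeds]
        results = {"typical": [], "atypical": []}
        for flag in ("typical", "atypical"):
            for _ in range(config.n_rest_per_group):
                run, _truth = syn.simulate_resting(
                    rest_spec, flag, seed=int(rng.integers(0, 2 ** 31 - 1)))
                clean = rc.preprocess_run(run)
                results[flag].append(rc.seed_connectivity(clean, analysis_seeds))
        contrast = rc.group_connectivity_contrast(results["typical"],
                                                  results["atypical"],
                                                  which="left_gt_right")
        gray = syn.make_tissue_masks(rest_spec.shape)["gray"]
        cl = rest_spec.asym_center_left_mm
        region_l = rc.sphere_mask(cl, rest_spec.asym_radius_mm,
                                  rest_spec.shape, rest_spec.affine)
        region_r = rc.sphere_mask((-cl[0], cl[1], cl[2]), rest_spec.asym_radius_mm,
                                  rest_spec.shape, rest_spec.affine)
        mean_l = float(contrast.data[region_l.data & gray.data].mean())
        mean_r = float(contrast.data[region_r.data & gray.data].mean())
        mean_all = float(contrast.data[gray.data].mean())
        report["restconn"] = {
            "settings": {"n_per_group": config.n_rest_per_group,
                         "n_volumes": rest_spec.n_volumes,
                         "tr_s": rest_spec.tr_s,
                         "band_hz": [rc.F_LO_HZ, rc.F_HI_HZ],
                         "contrast": "left_gt_right, typical - atypical"},
            "mean_t_region_left": _round(mean_l),
            "mean_t_region_right": _round(mean_r),
            "mean_t_gray": _round(mean_all),
        }
    else:
        report["warnings"].append("resting stage skipped: n_rest_per_group < 2")

    # --- evaluation against planted truth (analysis stages never read it) ---
    est_li = table["li"].to_numpy()
    planted = truth["realized_li"].to_numpy()
    eval_block = {"note": "estimates joined to generator truth; evaluation only"}
    if len(maps) >= 3 and np.ptp(planted) > 0:
        rec = st.pearson_with_df(planted, est_li)
        eval_block["planted_vs_estimated_li_r"] = _round(rec.r)
        eval_block["median_abs_li_error"] = _round(np.median(np.abs(planted - est_li)))
    true_groups = {row.subject_id: (0 if row.group == "left_typical" else 1)
                   for row in truth.itertuples()}
    if partition is not None:
        eval_block["graph_agreement_with_truth"] = _round(
            pg.partition_agreement(partition, true_groups))
    report["evaluation"] = eval_block

    if out_dir is not None:
        _write_outputs(Path(out_dir), report, table, truth)
    return report


def _write_outputs(out_dir: Path, report: dict, table, truth) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    table.to_csv(out_dir / "laterality.tsv", sep="\t", index=False)
    truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    with open(out_dir / "report.md", "w") as fh:
        fh.write(render_markdown(report))


def render_markdown(report: dict) -> str:
    """Human-readable summary of a run report."""
    lines = ["# Pipeline run report", ""]
    s = report["settings"]
    lines.append(f"Seed {s['seed']}, n = {s['n_subjects']}, "
                 f"extent coupling kappa = {s['extent_kappa']}, "
                 f"noise sd = {s['noise_sd']} Z.")
    lat_block = report.get("laterality")
    if lat_block:
        cc = lat_block["class_counts"]
        lines += ["", "## Laterality",
                  f"Classes: {cc['left_typical']} left-typical, "
                  f"{cc['bilateral']} bilateral, "
                  f"{cc['right_atypical']} right-atypical "
                  f"(band +/-{lat_block['settings']['band']})."]
    if "handedness_welch" in report:
        w = report["handedness_welch"]
        lines += ["", f"Typical right- vs left-handers: t({w['df']:.1f}) = "
                      f"{w['t']:.2f}, p = {w['p']:.3f}."]
    g = report.get("graph", {})
    if "n_communities" in g:
        lines += ["", "## Pattern graph",
                  f"{g['n_communities']} communities, Q = {g['modularity_q']:.3f}, "
                  f"agreement with LI labels = {g['agreement_with_li_labels']:.2f}."]
    if "extent" in report:
        e = report["extent"]
        lines += ["", "## Extent vs |LI|",
                  f"r({e['df']}) = {e['r']:.2f}, p = {e['p']:.3g}."]
    if "restconn" in report:
        r = report["restconn"]
        lines += ["", "## Resting connectivity",
                  f"Group contrast (L>R global signal, typical - atypical): "
                  f"mean t = {r['mean_t_region_left']:.2f} in the left planted "
                  f"region, {r['mean_t_region_right']:.2f} in the right, "
                  f"{r['mean_t_gray']:.2f} across gray matter."]
    if report.get("warnings"):
        lines += ["", "## Warnings"] + [f"- {w}" for w in report["warnings"]]
    return "\n".join(lines) + "\n"
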