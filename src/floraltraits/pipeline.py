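"""End-to-end analysis tracks: scent, reflectance, pollen chemistry.

Each track reproduces one analysis chain on a trait table or spectrum set:

* scent / chemistry: (optional relative-abundance normalisation) ->
  Bray-Curtis -> dispersion-homogeneity check -> perMANOVA + pairwise
  (Bonferroni) -> UPGMA with multiscale bootstrap -> indicator analysis;
* reflectance: spectra -> hexagon loci -> Euclidean loci matrix ->
  perMANOVA + pairwise -> species centroid distances with discrimination
  classes -> UPGMA on the loci distances.

The dispersion result is reported alongside the perMANOVA but never gates
it. Every artifact (square CSV matrices, Newick tree, TSV statistics) is
written to the output directory and a JSON report echoes the configuration,
seed and headline statistics; a run with identical config and seed is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import colorvision as cv
from . import hier_clustering as hc
from . import indicator_analysis as ia
from . import multivariate_stats as ms
from . import synthetic_data as sd
from . import trait_io as tio

__all__ = ["PipelineConfig", "run_track"]

REPORT_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    track: str  # scent | reflectance | chemistry | simulate
    input_path: str | None = None
    output_dir: str = "floraltraits_out"
    grouping: str = "species"
    distance: str = "bray_curtis"
    n_perm: int = 999
    scales: tuple[float, ...] = hc.DEFAULT_SCALES
    n_boot: int = 1000
    alpha: float = 0.05
    thresholds: tuple[float, float] = cv.DEFAULT_THRESHOLDS
    sensitivities_path: str | None = None
    illuminant_path: str | None = None
    background_path: str | None = None
    seed: int = 0
    normalise: bool = True  # scent track: convert to relative abundances
    simulate_kind: str = "scent"  # for track="simulate"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("scales", "thresholds"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _log(report: dict, stage: str, t0: float, shape) -> None:
    # report.json stays deterministic; wall times go to pipeline.log
    report["stages"].append({"stage": stage, "shape": list(shape)})
    out = Path(report["config"]["output_dir"])
    with open(out / "pipeline.log", "a") as fh:
        fh.write(
            f"stage={stage} wall_s={time.perf_counter() - t0:.4f} "
            f"shape={tuple(shape)} seed={report['seed']}\n"
        )


def _permanova_record(res: ms.PermanovaResult) -> dict:
    return {
        "SS_between": res.SS_A, "SS_within": res.SS_W, "SS_total": res.SS_T,
        "df": [res.df_between, res.df_within], "F": res.F, "R2": res.R2,
        "p": res.p, "n_perm": res.n_perm, "seed": res.seed,
        "warning": res.warning,
    }


def _vision_model(cfg: PipelineConfig) -> cv.VisionModel:
    grid = cv.DEFAULT_GRID
    sens = (
        tio.read_spectra(cfg.sensitivities_path, species_from_label=False)
        if cfg.sensitivities_path else cv.default_sensitivities(grid)
    )
    grid = sens.wavelengths_nm
    illum = (
        tio.read_spectra(cfg.illuminant_path).reflectance[0]
        if cfg.illuminant_path else cv.default_illuminant(grid)
    )
    backg = (
        tio.read_spectra(cfg.background_path).reflectance[0] / 100.0
        if cfg.background_path else cv.default_background(grid)
    )
    return cv.build_vision_model(sens, illum, backg)


def run_track(config: PipelineConfig) -> dict:
    """Run one analysis track; returns (and writes) the JSON report."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "track": config.track,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "seed": config.seed,
        "stages": [],
        "results": {},
    }
    try:
        if config.track == "simulate":
            _run_simulate(config, out, report)
        elif config.track in ("scent", "chemistry"):
            _run_composition(config, out, report)
        elif config.track == "reflectance":
            _run_reflectance(config, out, report)
        else:
            raise ValueError(f"unknown track {config.track!r}")
    except Exception as exc:
        (out / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        raise RuntimeError(f"stage failure in track {config.track!r}: {exc}") from exc
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def _run_simulate(cfg: PipelineConfig, out: Path, report: dict) -> None:
    t0 = time.perf_counter()
    if cfg.simulate_kind == "scent":
        table = sd.simulate_scent_profiles(sd.ScentSimSpec(seed=cfg.seed))
        tio.write_trait_table(table, out / "scent.csv")
        shape = table.values.shape
    elif cfg.simulate_kind == "spectra":
        spectra = sd.simulate_reflectance_spectra(sd.SpectraSimSpec(seed=cfg.seed))
        tio.write_spectra(spectra, out / "spectra.csv")
        shape = spectra.reflectance.shape
    elif cfg.simulate_kind == "chemistry":
        table = sd.simulate_pollen_chemistry(sd.table1_fixture(seed=cfg.seed))
        tio.write_trait_table(table, out / "chemistry.csv")
        shape = table.values.shape
    else:
        raise ValueError(f"unknown simulate kind {cfg.simulate_kind!r}")
    _log(report, f"simulate_{cfg.simulate_kind}", t0, shape)
    report["results"]["written"] = cfg.simulate_kind


def _run_composition(cfg: PipelineConfig, out: Path, report: dict) -> None:
    t0 = time.perf_counter()
    table = tio.read_trait_table(
        cfg.input_path, metadata_columns=("species", "bee_group"), units="concentration"
    )
    if cfg.track == "scent" and cfg.normalise:
        table = tio.to_relative_abundance(table)
    _log(report, "load", t0, table.values.shape)

    groups = table.groups(cfg.grouping)
    t0 = time.perf_counter()
    if cfg.distance == "bray_curtis":
        dm = ms.bray_curtis_matrix(table)
    elif cfg.distance == "euclidean":
        dm = ms.euclidean_matrix(table.values, table.sample_ids)
    else:
        raise ValueError(f"unknown distance {cfg.distance!r}")
    tio.write_square_matrix(dm, out / "distances.csv")
    _log(report, "distance", t0, dm.d.shape)

    t0 = time.perf_counter()
    disp = ms.dispersion_homogeneity(dm, groups, cfg.n_perm, cfg.seed + 1)
    report["results"]["dispersion"] = {
        "F": disp.F, "df": [disp.df_between, disp.df_within], "p": disp.p,
        "n_perm": disp.n_perm, "seed": disp.seed,
    }
    _log(report, "dispersion", t0, dm.d.shape)

    t0 = time.perf_counter()
    perm = ms.permanova(dm, groups, cfg.n_perm, cfg.seed + 2)
    report["results"]["permanova"] = _permanova_record(perm)
    pw = ms.pairwise_permanova(dm, groups, cfg.n_perm, cfg.seed + 3)
    pd.DataFrame(
        [
            {"group1": r.pair[0], "group2": r.pair[1], "F": r.F,
             "df_between": r.df_between, "df_within": r.df_within,
             "p_raw": r.p_raw, "p_adjusted": r.p_adjusted}
            for r in pw
        ]
    ).to_csv(out / "pairwise_permanova.tsv", sep="\t", index=False)
    report["results"]["pairwise_n"] = len(pw)
    _log(report, "permanova", t0, dm.d.shape)

    t0 = time.perf_counter()
    tree, supports = hc.multiscale_bootstrap(
        table, metric=cfg.distance, scales=cfg.scales,
        n_boot=cfg.n_boot, seed=cfg.seed + 4,
    )
    (out / "tree.nwk").write_text(hc.write_newick(tree, supports) + "\n")
    _support_table(tree, supports).to_csv(out / "node_support.tsv", sep="\t", index=False)
    report["results"]["clustering"] = {
        "n_leaves": tree.n_leaves,
        "min_AU": float(min(s.AU for s in supports)),
        "n_boot": cfg.n_boot, "scales": list(cfg.scales), "seed": cfg.seed + 4,
    }
    _log(report, "clustering", t0, table.values.shape)

    t0 = time.perf_counter()
    ind = ia.indval(table, groups, cfg.n_perm, cfg.seed + 5)
    ind.to_dataframe().to_csv(out / "indval.tsv", sep="\t", index=False)
    best = int(np.argmax(ind.indval))
    report["results"]["indval"] = {
        "top_variable": ind.variable_ids[best],
        "top_group": ind.best_group[best],
        "top_indval": float(ind.indval[best]),
        "top_p": float(ind.p[best]),
        "n_perm": ind.n_perm, "seed": ind.seed,
    }
    _log(report, "indval", t0, table.values.shape)


def _support_table(tree: hc.Dendrogram, supports: list[hc.NodeSupport]) -> pd.DataFrame:
    rows = []
    for s in supports:
        row = {"clade": "|".join(sorted(s.clade)), "AU": s.AU, "BP": s.BP,
               "v": s.v, "c": s.c, "fit_residual": s.fit_residual,
               "flag": s.flag}
        for r, bp in zip(s.scales, s.bp_per_scale):
            row[f"bp_r{r:g}"] = bp
        rows.append(row)
    return pd.DataFrame(rows)


def _run_reflectance(cfg: PipelineConfig, out: Path, report: dict) -> None:
    t0 = time.perf_counter()
    spectra = tio.read_spectra(cfg.input_path)
    model = _vision_model(cfg)
    loci = cv.spectra_to_loci(spectra, model)
    loci_df = pd.DataFrame(
        [
            {"label": l.label, "species": l.species,
             "E_UV": l.E[0], "E_B": l.E[1], "E_G": l.E[2], "x": l.x, "y": l.y}
            for l in loci
        ]
    )
    loci_df.to_csv(out / "hexagon_loci.csv", index=False)
    _log(report, "loci", t0, spectra.reflectance.shape)

    t0 = time.perf_counter()
    xy = loci_df[["x", "y"]].to_numpy()
    dm = ms.euclidean_matrix(xy, list(loci_df["label"]))
    tio.write_square_matrix(dm, out / "loci_distances.csv")
    if cfg.grouping == "species":
        groups = loci_df["species"].to_numpy()
    elif cfg.grouping == "bee_group":
        groups = _bee_groups(loci_df)
    else:
        raise ValueError(f"unknown grouping {cfg.grouping!r} for reflectance")
    perm = ms.permanova(dm, groups, cfg.n_perm, cfg.seed + 2)
    report["results"]["permanova"] = _permanova_record(perm)
    pw = ms.pairwise_permanova(dm, groups, cfg.n_perm, cfg.seed + 3)
    pd.DataFrame(
        [
            {"group1": r.pair[0], "group2": r.pair[1], "F": r.F,
             "df_between": r.df_between, "df_within": r.df_within,
             "p_raw": r.p_raw, "p_adjusted": r.p_adjusted}
            for r in pw
        ]
    ).to_csv(out / "pairwise_permanova.tsv", sep="\t", index=False)
    _log(report, "permanova", t0, dm.d.shape)

    t0 = time.perf_counter()
    cents = cv.species_centroid_distances(loci)
    tio.write_square_matrix(cents, out / "centroid_distances.csv")
    t_lo, t_hi = cfg.thresholds
    classes = []
    for i, s1 in enumerate(cents.labels):
        for j in range(i + 1, cents.n):
            dist = cents.d[i, j]
            cls = ("indistinguishable" if dist < t_lo
                   else "uncertain" if dist <= t_hi else "discriminable")
            classes.append({"species1": s1, "species2": cents.labels[j],
                            "distance_hexagon_units": dist, "class": cls})
    pd.DataFrame(classes).to_csv(out / "centroid_classes.tsv", sep="\t", index=False)
    report["results"]["centroids"] = {
        "n_pairs": len(classes),
        "n_discriminable": sum(c["class"] == "discriminable" for c in classes),
        "thresholds": list(cfg.thresholds),
    }
    _log(report, "centroids", t0, cents.d.shape)

    t0 = time.perf_counter()
    tree = hc.upgma(dm)
    (out / "tree.nwk").write_text(hc.write_newick(tree) + "\n")
    report["results"]["clustering"] = {"n_leaves": tree.n_leaves}
    _log(report, "clustering", t0, dm.d.shape)


def _bee_groups(loci_df: pd.DataFrame) -> np.ndarray:
    gm = sd.STUDY_GROUP_MAP
    return np.array([gm.get(sp, "none") for sp in loci_df["species"]])
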