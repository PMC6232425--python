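"""End-to-end analysis pipeline.

Runs, from a single configuration: data simulation (or ingest of measurement
and OTU tables), per-variable Hedges' g effect sizes, EAI aggregation with
CI-overlap letters, univariate ANOVA/Tukey per variable and timepoint,
community metrics (singleton removal, rarefaction, alpha diversity, UniFrac
distance matrices, PCoA), pairwise PERMANOVA per timepoint, and Type-I
variance partitioning of EAI against composition predictors. All outputs are
plain-text tables plus a JSON manifest sufficient to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, community, io, synthetic
from .eai import eai_table, summaries_to_frame, eai_report
from .effect_size import effect_size_table, estimates_to_frame
from .inference import one_way_anova, pairwise_permanova, tukey_hsd, variance_partition

log = logging.getLogger("ecoimpact")

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "study_like_config"]


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    out_dir: str = "ecoimpact_out"
    mode: str = "simulate"  # simulate | ingest
    seed: int = 0
    control_label: str = "control"
    # ingest-mode inputs
    measurements_path: str | None = None
    otu_table_path: str | None = None
    tree_path: str | None = None
    # analysis settings
    variables: list[str] | None = None  # None: all variables in the data
    transforms: dict[str, str] = field(default_factory=dict)
    eai_timepoints: list[str] | None = None  # None: every timepoint
    letters_within_timepoint: bool = True
    rarefaction_depth: int = 2200
    unifrac_metrics: list[str] = field(
        default_factory=lambda: ["weighted_unifrac", "unweighted_unifrac"]
    )
    permanova_metric: str = "weighted_unifrac"
    permutations: int = 999
    varpart_predictors: list[str] = field(default_factory=list)
    continue_on_error: bool = False
    # simulate-mode scenario
    n_replicates: int = 4
    timepoints: list[str] = field(
        default_factory=lambda: ["T0", "T1", "T2", "T3", "T4"]
    )
    effects: dict = field(default_factory=dict)  # treatment -> timepoint -> delta scale
    n_otus: int = 300
    depth_range: tuple[int, int] = (2500, 5000)
    alpha_total: float = 50.0
    shift_fraction: float = 0.3
    shift_logfold_per_delta: float = 0.5

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.mode not in ("simulate", "ingest"):
            raise ValueError(f"unknown mode {cfg.mode!r}")
        if cfg.rarefaction_depth <= 0:
            raise ValueError("rarefaction depth must be positive")
        if cfg.mode == "ingest":
            for key in ("measurements_path", "otu_table_path", "tree_path"):
                p = getattr(cfg, key)
                if p is not None and not Path(p).exists():
                    raise ValueError(f"{key} does not exist: {p}")
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["depth_range"] = list(self.depth_range)
        return d


def study_like_config(out_dir: str, seed: int = 0) -> RunConfig:
    """The bundled study-like scenario: control + 3 repeated disturbances +
    6 chronology treatments, 4 replicates, 5 timepoints, 26 variables,
    300 OTUs, rarefaction to 2200 reads.

    Planted per-variable standardized effects grow after the disturbance
    sequence (zero at T0) and differ between chronologies, spanning weak to
    strong aggregated impacts; community alpha shifts scale with the same
    per-cell effect so composition change tracks functional change.
    """
    ramp = {"T0": 0.0, "T1": 0.4, "T2": 0.7, "T3": 1.0, "T4": 1.2}
    strength = {
        "F": 0.6,
        "H": 0.8,
        "A": 1.0,
        "FHA": 1.2,
        "FAH": 1.0,
        "HFA": 1.4,
        "HAF": 0.8,
        "AFH": 2.2,
        "AHF": 1.8,
    }
    effects = {
        trt: {tp: s * r for tp, r in ramp.items()} for trt, s in strength.items()
    }
    return RunConfig(
        out_dir=out_dir,
        mode="simulate",
        seed=seed,
        effects=effects,
        shift_logfold_per_delta=1.0,
        alpha_total=400.0,
        eai_timepoints=["T1", "T2", "T3", "T4"],
        varpart_predictors=[
            "weighted_unifrac",
            "qnosZI",
            "qnosZII",
            "observed_species",
            "faith_pd",
            "simpson_reciprocal",
        ],
    )


def _expand_effects(
    design: synthetic.ExperimentDesign, effects: dict
) -> dict[tuple[str, str, str], float]:
    """Per-cell delta scales -> per-variable EffectSpec with alternating
    signs (the index folds signs away; alternating exercises that)."""
    spec: dict[tuple[str, str, str], float] = {}
    for trt, per_tp in effects.items():
        for tp, scale in per_tp.items():
            for i, name in enumerate(design.variable_names):
                spec[(trt, tp, name)] = float(scale) * (1 if i % 2 == 0 else -1)
    return spec


def _stage(name, manifest, continue_on_error):
    class _Ctx:
        def __enter__(self):
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is None:
                manifest["stages"][name] = "ok"
                log.info("stage %s: done", name)
                return False
            manifest["stages"][name] = f"failed: {exc}"
            log.error("stage %s: failed: %s", name, exc)
            if continue_on_error:
                return True
            raise PipelineError(name, exc) from exc

    return _Ctx()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the report bundle; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "stages": {},
        "outputs": [],
    }

    def save(name: str) -> Path:
        manifest["outputs"].append(name)
        return out / name

    root = np.random.SeedSequence(config.seed)
    seed_measurements, seed_communities, seed_rarefy, seed_permanova = (
        int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(4)
    )

    measurements = otu = tree = None
    with _stage("data", manifest, config.continue_on_error):
        if config.mode == "simulate":
            design = synthetic.default_design(
                n_replicates=config.n_replicates, timepoints=config.timepoints
            )
            measurements = synthetic.simulate_measurements(
                design, _expand_effects(design, config.effects), seed_measurements
            )
            shift = {
                (trt, tp): (
                    config.shift_fraction,
                    config.shift_logfold_per_delta * scale,
                )
                for trt, per_tp in config.effects.items()
                for tp, scale in per_tp.items()
                if scale != 0.0
            }
            cspec = synthetic.CommunitySpec(
                n_otus=config.n_otus,
                alpha_total=config.alpha_total,
                depth_range=tuple(config.depth_range),
                shift=shift,
            )
            otu, tree = synthetic.simulate_communities(design, cspec, seed_communities)
            io.write_measurements(measurements, save("measurements.tsv"))
            community.write_otu_table(otu, save("otu_table.tsv"))
            tree.write(str(save("tree.nwk")))
            if config.variables is None:
                config = dataclasses.replace(config, variables=design.variable_names)
            if not config.transforms:
                config = dataclasses.replace(config, transforms=design.transform_map)
        else:
            if config.measurements_path:
                measurements = io.read_measurements(config.measurements_path)
            if config.otu_table_path:
                otu = community.read_otu_table(config.otu_table_path)
            if config.tree_path:
                tree = community.read_tree(config.tree_path)
        if measurements is not None and config.variables is None:
            config = dataclasses.replace(
                config, variables=sorted(measurements["variable"].unique())
            )

    estimates = None
    if measurements is not None:
        with _stage("effect_sizes", manifest, config.continue_on_error):
            estimates = effect_size_table(
                measurements,
                config.control_label,
                config.variables,
                config.transforms,
            )
            estimates_to_frame(estimates).to_csv(
                save("effect_sizes.tsv"), sep="\t", index=False
            )

    summaries = None
    if estimates is not None:
        with _stage("eai", manifest, config.continue_on_error):
            kept = [
                e
                for e in estimates
                if config.eai_timepoints is None
                or e.timepoint in config.eai_timepoints
            ]
            summaries = eai_table(
                kept,
                config.variables,
                letters_within_timepoint=config.letters_within_timepoint,
            )
            eai_report(summaries, save("eai.tsv"))

    if measurements is not None:
        with _stage("univariate", manifest, config.continue_on_error):
            anova_rows, tukey_frames = [], []
            for (tp, var), sub in measurements.groupby(["timepoint", "variable"]):
                if var not in config.variables:
                    continue
                vals = sub["value"].to_numpy(dtype=float)
                if config.transforms.get(var) == "log10":
                    vals = np.log10(vals)
                res = one_way_anova(vals, sub["treatment"])
                anova_rows.append(
                    {
                        "timepoint": tp,
                        "variable": var,
                        "F": res.F,
                        "df_between": res.df_between,
                        "df_within": res.df_within,
                        "p": res.p,
                    }
                )
                tk = tukey_hsd(vals, sub["treatment"])
                tk.insert(0, "variable", var)
                tk.insert(0, "timepoint", tp)
                tukey_frames.append(tk)
            pd.DataFrame(anova_rows).to_csv(save("anova.tsv"), sep="\t", index=False)
            pd.concat(tukey_frames, ignore_index=True).to_csv(
                save("tukey.tsv"), sep="\t", index=False
            )

    rarefied = None
    dms: dict[str, object] = {}
    if otu is not None and tree is not None:
        with _stage("community", manifest, config.continue_on_error):
            filtered = community.remove_singletons(otu)
            deep_enough = filtered.sum(axis=1) >= config.rarefaction_depth
            dropped = filtered.index[~deep_enough].tolist()
            if dropped:
                log.warning("excluding %d sample(s) below depth", len(dropped))
            manifest["samples_below_depth"] = dropped
            rarefied = community.rarefy_table(
                filtered.loc[deep_enough], config.rarefaction_depth, seed_rarefy
            )
            community.write_otu_table(rarefied, save("rarefied_otu_table.tsv"))
            community.alpha_diversity_table(rarefied, tree).to_csv(
                save("alpha_diversity.tsv"), sep="\t"
            )
            for metric in config.unifrac_metrics:
                dm = community.distance_matrix(rarefied, tree, metric)
                dms[metric] = dm
                io.write_distance_matrix(dm, save(f"distance_{metric}.tsv"))
                coords, eigvals = community.pcoa(dm)
                io.write_pcoa(coords, eigvals, save(f"pcoa_{metric}.tsv"))

    if dms:
        with _stage("permanova", manifest, config.continue_on_error):
            dm = dms.get(config.permanova_metric)
            if dm is None:
                raise ValueError(
                    f"permanova metric {config.permanova_metric!r} not computed"
                )
            meta = _sample_meta(dm.ids)
            frames = []
            for tp in sorted(meta["timepoint"].unique()):
                ids = meta.index[meta["timepoint"] == tp]
                sub = dm.filter(ids)
                res = pairwise_permanova(
                    sub,
                    meta.loc[ids, "treatment"].to_numpy(),
                    config.permutations,
                    seed_permanova,
                )
                res.insert(0, "timepoint", tp)
                frames.append(res)
            pd.concat(frames, ignore_index=True).to_csv(
                save("pairwise_permanova.tsv"), sep="\t", index=False
            )

    if summaries is not None and config.varpart_predictors:
        with _stage("varpart", manifest, config.continue_on_error):
            table = _varpart_table(config, summaries, estimates, dms)
            table.to_csv(save("variance_partition.tsv"), sep="\t", index=False)

    with _stage("manifest", manifest, config.continue_on_error):
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _sample_meta(ids) -> pd.DataFrame:
    rows = {}
    for sid in ids:
        treatment, timepoint, _rep = str(sid).rsplit(".", 2)
        rows[sid] = {"treatment": treatment, "timepoint": timepoint}
    return pd.DataFrame.from_dict(rows, orient="index")


def _varpart_table(config, summaries, estimates, dms) -> pd.DataFrame:
    """EAI per (treatment, timepoint) cell regressed on ordered predictors:
    a distance metric name means the mean rarefied-community distance from
    that cell's samples to the same-timepoint control samples; any other
    name is |Hedges' g| of that variable in the cell."""
    cells = [(s.treatment, s.timepoint) for s in summaries]
    response = [s.eai for s in summaries]
    g_lookup = {(e.treatment, e.timepoint, e.variable): abs(e.g) for e in estimates}

    predictors: dict[str, list[float]] = {}
    for name in config.varpart_predictors:
        col = []
        if name in dms:
            dm = dms[name]
            meta = _sample_meta(dm.ids)
            for trt, tp in cells:
                trt_ids = meta.index[
                    (meta["treatment"] == trt) & (meta["timepoint"] == tp)
                ]
                ctl_ids = meta.index[
                    (meta["treatment"] == config.control_label)
                    & (meta["timepoint"] == tp)
                ]
                if len(trt_ids) == 0 or len(ctl_ids) == 0:
                    raise ValueError(
                        f"no samples for varpart cell ({trt!r}, {tp!r})"
                    )
                block = dm.between(list(trt_ids), list(ctl_ids))
                col.append(float(block["value"].mean()))
        else:
            for trt, tp in cells:
                key = (trt, tp, name)
                if key not in g_lookup:
                    raise ValueError(f"varpart predictor {name!r} missing for {key}")
                col.append(g_lookup[key])
        predictors[name] = col
    return variance_partition(response, predictors)
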