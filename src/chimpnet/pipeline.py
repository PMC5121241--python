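"""End-to-end orchestration: generate/ingest -> measure -> network -> inference.

:func:`run_pipeline` takes a :class:`RunConfig` and writes a complete, reproducible
result bundle: input tables (generated or copied through validation), dyadic rate
matrices, the four proximity-bond networks, centrality tables, MRQAP and node-level
regression tables, Geary's C results, and a run manifest with the config, seed and
stage timings. Re-running with the same config reproduces every number.

The MRQAP model menu mirrors the standard analysis sequence: a dyad-attribute
control model (kin, age-class, sex, reproductive similarity), then grooming added,
then all per-function gesture rates and grooming in one model.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from . import measures as cm
from . import networks as cn
from . import permstats as ps
from . import synth
from .records import GROOMING_CATEGORIES, PANT_GRUNT, SEQUENCE_FUNCTIONS, PANT_HOOT_FUNCTIONS

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("chimpnet.pipeline")

SIMILARITY_KINDS = ("kin", "age_class", "sex", "reproductive")

DEFAULT_MODELS: dict[str, list[str]] = {
    "attributes": list(SIMILARITY_KINDS),
    "attributes+grooming": list(SIMILARITY_KINDS)
    + [f"grooming:{c}" for c in GROOMING_CATEGORIES],
    "attributes+grooming+gestures": list(SIMILARITY_KINDS)
    + [f"grooming:{c}" for c in GROOMING_CATEGORIES]
    + [f"communication:{f}" for f in SEQUENCE_FUNCTIONS + PANT_HOOT_FUNCTIONS],
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of one end-to-end run (YAML-serializable)."""

    output_dir: str = "chimpnet-run"
    seed: int = 0
    # either generate synthetically (default) or read these three paths
    scans_path: str | None = None
    events_path: str | None = None
    attributes_path: str | None = None
    mrqap_permutations: int = 2000
    nodereg_permutations: int = 10_000
    geary_permutations: int = 2000
    mrqap_models: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_MODELS.items()}
    )
    bonferroni: bool = False

    def validate(self, available_predictors: set[str] | None = None) -> None:
        for name, count in (
            ("mrqap_permutations", self.mrqap_permutations),
            ("nodereg_permutations", self.nodereg_permutations),
            ("geary_permutations", self.geary_permutations),
        ):
            if count < 99:
                raise PipelineError(f"config: {name} must be at least 99, got {count}")
        paths = (self.scans_path, self.events_path, self.attributes_path)
        if any(paths) and not all(paths):
            raise PipelineError(
                "config: provide all of scans/events/attributes paths, or none"
            )
        if available_predictors is not None:
            for model, preds in self.mrqap_models.items():
                unknown = [p for p in preds if p not in available_predictors]
                if unknown:
                    raise PipelineError(
                        f"config: model {model!r} references unknown predictors {unknown}"
                    )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise PipelineError(f"config: unknown keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _available_predictor_names() -> set[str]:
    return (
        set(SIMILARITY_KINDS)
        | {f"grooming:{c}" for c in GROOMING_CATEGORIES}
        | {f"communication:{f}" for f in SEQUENCE_FUNCTIONS + PANT_HOOT_FUNCTIONS}
        | {"communication:all-gestures", f"communication:{PANT_GRUNT}"}
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the result bundle; returns key in-memory results."""
    config.validate(_available_predictor_names())
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    timings: dict[str, float] = {}
    results: dict = {}

    def stage(name: str):
        class _Stage:
            def __enter__(self_inner):
                log.info("stage %s: start", name)
                self_inner.t0 = time.perf_counter()

            def __exit__(self_inner, exc_type, exc, tb):
                dt = time.perf_counter() - self_inner.t0
                timings[name] = round(dt, 3)
                if exc is not None:
                    log.error("stage %s: FAILED after %.2fs: %s", name, dt, exc)
                    (out / "FAILED").write_text(f"stage {name}: {exc}\n")
                    raise PipelineError(f"stage {name!r} failed: {exc}") from exc
                log.info("stage %s: done in %.2fs", name, dt)

        return _Stage()

    # -- inputs ------------------------------------------------------------
    with stage("inputs"):
        if config.scans_path:
            attrs = cio.read_attributes(config.attributes_path)
            known = set(attrs["id"])
            scans = cio.read_scans(config.scans_path, known_ids=known)
            events = cio.read_events(config.events_path, known_ids=known)
        else:
            cconf = synth.CommunityConfig(seed=config.seed)
            attrs, _model, scans, events = synth.generate_dataset(cconf)
        cio.write_attributes(attrs, out / "attributes.csv")
        cio.write_scans(scans, out / "scans.csv")
        cio.write_events(events, out / "events.csv")
        focal_ids = sorted(attrs.loc[attrs.is_focal, "id"])

    # -- measures ----------------------------------------------------------
    with stage("measures"):
        counts = cm.count_dyads(scans)
        sequences = cm.assemble_sequences(events)
        comm_counts = cm.count_sequences(sequences, events)
        kin_pairs = {
            frozenset({row.id, k})
            for row in attrs.itertuples()
            for k in str(row.kin_ids).split(";")
            if k
        }
        oestrous = set(attrs.loc[attrs.oestrous, "id"])
        matrices: dict[str, object] = {}
        matrices["proximity"] = cm.association_matrix(counts, focal_ids)
        matrices["proximity:kin"] = cm.association_matrix(
            counts, focal_ids, kin_pairs=kin_pairs, label="proximity:kin"
        )
        matrices["proximity:oestrus"] = cm.association_matrix(
            counts, focal_ids, oestrous_ids=oestrous, label="proximity:oestrus"
        )
        for c in GROOMING_CATEGORIES:
            matrices[f"grooming:{c}"] = cm.grooming_matrix(counts, c, focal_ids)
        for f in SEQUENCE_FUNCTIONS + PANT_HOOT_FUNCTIONS + (PANT_GRUNT,):
            matrices[f"communication:{f}"] = cm.communication_matrix(
                comm_counts, counts, f, focal_ids
            )
        matrices["communication:all-gestures"] = cm.combined_gesture_matrix(
            comm_counts, counts, focal_ids
        )
        for kind in SIMILARITY_KINDS:
            matrices[kind] = cn.similarity_matrix(
                attrs[attrs.is_focal].reset_index(drop=True), kind
            )
        mdir = out / "matrices"
        mdir.mkdir(exist_ok=True)
        for name, m in matrices.items():
            cio.write_matrix(m, mdir / f"{name.replace(':', '_').replace(' ', '-')}.csv")
        cm.measure_table(
            [matrices["proximity"]]
            + [matrices[f"grooming:{c}"] for c in GROOMING_CATEGORIES]
            + [matrices["communication:all-gestures"]]
        ).to_csv(out / "measures.csv", index=False)
        results["matrices"] = matrices

    # -- networks ----------------------------------------------------------
    with stage("networks"):
        bonds, thresholds = cn.classify_bonds(matrices["proximity"])
        ndir = out / "networks"
        ndir.mkdir(exist_ok=True)
        degree_rows = []
        for cls_name in cn.BOND_CLASSES:
            m = bonds[cls_name]
            cio.write_matrix(m, ndir / f"bond_{cls_name}.csv")
            cio.export_edges(m, ndir / f"bond_{cls_name}_edges.csv")
            cio.write_graphml(m, ndir / f"bond_{cls_name}.graphml")
        # dichotomized-symmetrized mean degrees of the four headline networks
        dens = {}
        groom_any = matrices["grooming:given"].copy()
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN diagonal
            stack = np.nanmax(
                np.stack(
                    [matrices[f"grooming:{c}"].values for c in GROOMING_CATEGORIES]
                ),
                axis=0,
            )
        groom_any.values = stack
        groom_any.label = "grooming:any"
        headline = {
            "proximity": matrices["proximity"],
            "gesture": matrices["communication:all-gestures"],
            "grooming": groom_any,
            "pant-grunt": matrices[f"communication:{PANT_GRUNT}"],
        }
        for name, m in headline.items():
            sym = cn.symmetrize_or(cn.dichotomize(m))
            md, (lo, hi) = cn.mean_degree(sym)
            dens[name] = {"mean_degree_pct": md, "min_pct": lo, "max_pct": hi}
        for direction in ("in", "out"):
            for name, m in list(headline.items()) + [
                ("preferred_partner", bonds.preferred_partner)
            ]:
                for node, v in cn.degree_centrality(m, direction).items():
                    degree_rows.append(
                        {"network": name, "direction": direction, "id": node, "degree": v}
                    )
        pd.DataFrame(degree_rows).to_csv(out / "centrality.csv", index=False)
        with open(out / "network_summary.json", "w") as fh:
            json.dump(
                {
                    "bond_thresholds": {
                        "mean": thresholds.mean,
                        "sd": thresholds.sd,
                        "upper": thresholds.upper,
                        "lower": thresholds.lower,
                    },
                    "mean_degrees": dens,
                },
                fh,
                indent=2,
            )
        results["bonds"] = bonds
        results["mean_degrees"] = dens

    # -- MRQAP -------------------------------------------------------------
    with stage("mrqap"):
        tables = []
        for model_name, preds in config.mrqap_models.items():
            res = ps.mrqap_dsp(
                matrices["proximity"],
                [matrices[p] for p in preds],
                n_perm=config.mrqap_permutations,
                seed=config.seed,
            )
            t = res.to_frame()
            t.insert(0, "model", model_name)
            if config.bonferroni:
                t["p_bonferroni"] = res.bonferroni()
            tables.append(t)
        mrqap_table = pd.concat(tables, ignore_index=True)
        mrqap_table.to_csv(out / "mrqap.csv", index=False)
        results["mrqap"] = mrqap_table

    # -- node-level regression --------------------------------------------
    with stage("nodereg"):
        outcome = cn.degree_centrality(bonds.preferred_partner, "in")
        at = attrs.set_index("id").loc[focal_ids]
        predictors = pd.DataFrame(
            {
                "gesture_out_degree": cn.degree_centrality(
                    matrices["communication:all-gestures"], "out"
                ),
                "pant_grunt_out_degree": cn.degree_centrality(
                    matrices[f"communication:{PANT_GRUNT}"], "out"
                ),
                "sex_male": (at["sex"] == "M").astype(float),
                "age_years": at["age_years"].astype(float),
            }
        )
        res = ps.node_regression(
            outcome, predictors, n_perm=config.nodereg_permutations, seed=config.seed
        )
        res.to_frame().to_csv(out / "node_regression.csv", index=False)
        results["nodereg"] = res

    # -- Geary's C ---------------------------------------------------------
    with stage("geary"):
        minutes = attrs.set_index("id").loc[focal_ids, "minutes_observed"].astype(float)
        g = ps.gearys_c(
            minutes,
            matrices["proximity"],
            n_perm=config.geary_permutations,
            seed=config.seed,
        )
        with open(out / "geary.json", "w") as fh:
            json.dump(
                {
                    "attribute": "minutes_observed",
                    "network": "proximity",
                    "C": g.c,
                    "direction": g.direction,
                    "p_perm": g.p_perm,
                    "null_mean": g.null_mean,
                    "n_perm": g.n_perm,
                    "seed": g.seed,
                },
                fh,
                indent=2,
            )
        results["geary"] = g

    # -- manifest ----------------------------------------------------------
    from . import __version__

    with open(out / "manifest.json", "w") as fh:
        json.dump(
            {
                "config": asdict(config),
                "chimpnet_version": __version__,
                "stage_seconds": timings,
            },
            fh,
            indent=2,
        )
    log.removeHandler(handler)
    handler.close()
    return results
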