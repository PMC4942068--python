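"""Config-driven end-to-end runs of the correlation-network analysis.

A run is a set of named binding conditions (each a topology + trajectory,
real or synthetic) pushed through the stage graph

    simulate → energies → correlate → project → consensus → hotspots
                                                          → cluster
    occupancy, tilt, compare                    (geometry side)

Each stage writes delimited-text artifacts plus a log line with input
hashes, parameters and the seed; a rerun with an identical config is
bit-identical. Stages are cached by content hash of their inputs and
parameters and re-run only when those change.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import correlation_network as cn
from . import structure_geometry as sg
from .cg_system import (
    NonbondedTable,
    SelectionConfig,
    Topology,
    load_topology,
    load_trajectory,
    write_pdb,
)
from .interaction_energy import InteractionEnergySeries, energy_series
from .synthetic_data import (
    SyntheticSpec,
    default_selection,
    make_coupled_series,
    make_ligand_trajectory,
    make_toy_pentamer,
    write_manifest,
)

__all__ = ["RunConfig", "PipelineError", "DependencyError", "run_pipeline", "STAGES"]

logger = logging.getLogger("allonet.pipeline")

STAGES = (
    "simulate",
    "energies",
    "correlate",
    "project",
    "consensus",
    "hotspots",
    "cluster",
    "occupancy",
    "tilt",
    "compare",
)


class PipelineError(RuntimeError):
    pass


class DependencyError(PipelineError):
    """A stage's upstream artifact is missing."""


@dataclass
class Thresholds:
    mean_energy_kjmol: float = cn.MEAN_ENERGY_THRESHOLD_KJMOL
    correlation: float = cn.CORRELATION_THRESHOLD
    occupancy_cutoff_nm: float = 0.7
    hotspot_percentile: float = 75.0
    n_clusters: int = 10

    def validate(self) -> None:
        if self.mean_energy_kjmol < 0:
            raise ValueError("mean_energy_kjmol must be >= 0")
        if not (0.0 <= self.correlation < 1.0):
            raise ValueError("correlation threshold must lie in [0, 1)")
        if self.occupancy_cutoff_nm <= 0:
            raise ValueError("occupancy_cutoff_nm must be positive")
        if not (0.0 <= self.hotspot_percentile <= 100.0):
            raise ValueError("hotspot_percentile must lie in [0, 100]")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")


@dataclass
class ConditionConfig:
    name: str
    topology: str | None = None
    trajectory: str | None = None
    synthetic: dict | None = None


@dataclass
class RunConfig:
    output_dir: str = "allonet_out"
    seed: int = 0
    stride: int = 1
    reference_condition: str | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    nonbonded_table: str | None = None
    selection: str | None = None
    conditions: list[ConditionConfig] = field(default_factory=list)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        thr = Thresholds(**(raw.get("thresholds") or {}))
        conds = [
            ConditionConfig(name=str(name), **(spec or {}))
            for name, spec in (raw.get("conditions") or {}).items()
        ]
        return cls(
            output_dir=raw.get("output_dir", "allonet_out"),
            seed=int(raw.get("seed", 0)),
            stride=int(raw.get("stride", 1)),
            reference_condition=raw.get("reference_condition"),
            thresholds=thr,
            nonbonded_table=raw.get("nonbonded_table"),
            selection=raw.get("selection"),
            conditions=conds,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def validate(self) -> None:
        self.thresholds.validate()
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if not self.conditions:
            raise ValueError("no conditions configured")
        names = [c.name for c in self.conditions]
        if len(set(names)) != len(names):
            raise ValueError("duplicate condition names")
        if self.reference_condition is not None and self.reference_condition not in names:
            raise ValueError(
                f"reference_condition {self.reference_condition!r} is not a condition"
            )
        for c in self.conditions:
            if c.synthetic is None:
                if not c.topology or not c.trajectory:
                    raise ValueError(
                        f"condition {c.name!r} needs topology+trajectory or synthetic"
                    )
                for p in (c.topology, c.trajectory):
                    if not Path(p).exists():
                        raise ValueError(f"input path does not exist: {p}")
        for p in (self.nonbonded_table, self.selection):
            if p is not None and not Path(p).exists():
                raise ValueError(f"input path does not exist: {p}")

    def condition(self, name: str) -> ConditionConfig:
        for c in self.conditions:
            if c.name == name:
                return c
        raise KeyError(name)

    def reference(self) -> str:
        return self.reference_condition or self.conditions[0].name


# ---------------------------------------------------------------------------
# artifact bookkeeping


def _hash_bytes(*parts: bytes) -> str:
    h = hashlib.sha256()
    for p in parts:
        h.update(p)
    return h.hexdigest()


def _params_hash(obj) -> bytes:
    return json.dumps(obj, sort_keys=True, default=str).encode()


class _Store:
    """Artifact directory with hash-based caching."""

    def __init__(self, root: Path, seed: int):
        self.root = root
        self.seed = seed
        root.mkdir(parents=True, exist_ok=True)
        self.produced: dict[str, list[str]] = {}

    def path(self, name: str) -> Path:
        return self.root / name

    def fresh(self, name: str, input_hash: str) -> bool:
        """True if the artifact exists and was built from the same inputs."""
        art, meta = self.path(name), self.path(name + ".meta.json")
        if not (art.exists() and meta.exists()):
            return False
        try:
            return json.loads(meta.read_text())["input_hash"] == input_hash
        except (json.JSONDecodeError, KeyError):
            return False

    def record(self, stage: str, name: str, input_hash: str, params: dict) -> Path:
        meta = {"stage": stage, "input_hash": input_hash, "params": params, "seed": self.seed}
        self.path(name + ".meta.json").write_text(json.dumps(meta, sort_keys=True, default=str))
        self.produced.setdefault(stage, []).append(name)
        logger.info("stage=%s artifact=%s input_hash=%s params=%s seed=%d",
                    stage, name, input_hash[:12], params, self.seed)
        return self.path(name)

    def reuse(self, stage: str, *names: str) -> None:
        """List cached artifacts in the run report without rebuilding them."""
        for name in names:
            if self.path(name).exists():
                self.produced.setdefault(stage, []).append(name)
                logger.info("stage=%s artifact=%s cached", stage, name)

    def require(self, stage: str, name: str) -> Path:
        p = self.path(name)
        if not p.exists():
            raise DependencyError(
                f"stage {stage!r} requires missing artifact {name!r}; "
                "run its upstream stage first"
            )
        return p


def _file_hash(path: Path) -> bytes:
    return hashlib.sha256(path.read_bytes()).digest()


# ---------------------------------------------------------------------------
# per-stage helpers


def _condition_seed(config: RunConfig, cond_index: int) -> int:
    return (config.seed * 1000 + cond_index) % (2**31 - 1)


def _load_condition_system(config: RunConfig, cond: ConditionConfig, store: _Store):
    """Topology + trajectory for a condition, from files or simulate artifacts."""
    if cond.synthetic is not None:
        topo_p = store.require("energies", f"{cond.name}_topology.pdb")
        traj_p = store.require("energies", f"{cond.name}_trajectory.pdb")
    else:
        topo_p, traj_p = Path(cond.topology), Path(cond.trajectory)
    topo = load_topology(topo_p)
    traj = load_trajectory(traj_p, topo)
    return topo, traj


def _selection_for(config: RunConfig, cond: ConditionConfig) -> SelectionConfig:
    if config.selection is not None:
        return SelectionConfig.from_yaml(config.selection)
    if cond.synthetic is not None:
        spec = _spec_for(config, cond)
        return default_selection(spec)
    raise PipelineError(
        f"condition {cond.name!r}: no selection config given and none derivable"
    )


def _spec_for(config: RunConfig, cond: ConditionConfig) -> SyntheticSpec:
    raw = dict(cond.synthetic or {})
    idx = [c.name for c in config.conditions].index(cond.name)
    raw.setdefault("seed", _condition_seed(config, idx))
    raw["planted_modules"] = [
        dict(m) if not isinstance(m, dict) else m for m in raw.get("planted_modules", [])
    ]
    raw["contact_plan"] = [tuple(p) for p in raw.get("contact_plan", [])]
    raw["tilt_schedule"] = {
        (str(k).split(":")[0], str(k).split(":")[1]): v
        for k, v in (raw.get("tilt_schedule") or {}).items()
    } if raw.get("tilt_schedule") else {}
    return SyntheticSpec(**raw)


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(config: RunConfig, store: _Store) -> None:
    for cond in config.conditions:
        if cond.synthetic is None:
            continue
        spec = _spec_for(config, cond)
        ihash = _hash_bytes(_params_hash(spec.manifest()))
        topo_name = f"{cond.name}_topology.pdb"
        traj_name = f"{cond.name}_trajectory.pdb"
        if store.fresh(topo_name, ihash) and store.fresh(traj_name, ihash):
            store.reuse("simulate", topo_name, traj_name,
                        f"{cond.name}_manifest.yaml", f"{cond.name}_energies.tsv",
                        f"{cond.name}_series_manifest.yaml")
            continue
        topo, traj = make_toy_pentamer(spec)
        if spec.contact_plan:
            topo, traj = make_ligand_trajectory(
                traj, topo, spec.contact_plan, cutoff=spec.occupancy_cutoff,
                seed=spec.seed + 1,
            )
        write_pdb(store.path(topo_name), topo, traj.__class__(traj.coordinates[:1], traj.box[:1]))
        write_pdb(store.path(traj_name), topo, traj)
        write_manifest(store.path(f"{cond.name}_manifest.yaml"), spec.manifest())
        params = {"condition": cond.name}
        store.record("simulate", topo_name, ihash, params)
        store.record("simulate", traj_name, ihash, params)
        store.record("simulate", f"{cond.name}_manifest.yaml", ihash, params)
        if spec.planted_modules:
            series, manifest = make_coupled_series(spec)
            sname = f"{cond.name}_energies.tsv"
            series.save(store.path(sname))
            write_manifest(store.path(f"{cond.name}_series_manifest.yaml"), manifest)
            store.record("simulate", sname, ihash, params)
            store.record("simulate", f"{cond.name}_series_manifest.yaml", ihash, params)


def _stage_energies(config: RunConfig, store: _Store) -> None:
    for cond in config.conditions:
        name = f"{cond.name}_energies.tsv"
        if cond.synthetic is not None and store.path(name).exists():
            # planted series written by simulate is the energies artifact
            store.reuse("energies", name)
            continue
        if cond.synthetic is None:
            topo_p, traj_p = Path(cond.topology), Path(cond.trajectory)
        else:
            topo_p = store.require("energies", f"{cond.name}_topology.pdb")
            traj_p = store.require("energies", f"{cond.name}_trajectory.pdb")
        if config.nonbonded_table is None:
            raise PipelineError(
                f"condition {cond.name!r}: energies stage needs a nonbonded_table"
            )
        table_p = Path(config.nonbonded_table)
        ihash = _hash_bytes(
            _file_hash(topo_p), _file_hash(traj_p), _file_hash(table_p),
            _params_hash({"stride": config.stride}),
        )
        if store.fresh(name, ihash):
            store.reuse("energies", name)
            continue
        topo = load_topology(topo_p)
        traj = load_trajectory(traj_p, topo)
        table = NonbondedTable.from_csv(table_p)
        sel_chains: tuple[str, ...] = ()
        try:
            sel = _selection_for(config, cond)
            sel_chains = tuple(sel.ligand_chain_ids)
        except PipelineError:
            pass
        series = energy_series(
            traj, topo, table, stride=config.stride, exclude_chains=sel_chains
        )
        series.save(store.path(name))
        store.record("energies", name, ihash, {"condition": cond.name, "stride": config.stride})


def _stage_correlate(config: RunConfig, store: _Store) -> None:
    thr = config.thresholds
    for cond in config.conditions:
        src = store.require("correlate", f"{cond.name}_energies.tsv")
        ihash = _hash_bytes(
            _file_hash(src),
            _params_hash({"mean": thr.mean_energy_kjmol, "cmin": thr.correlation}),
        )
        rname = f"{cond.name}_retained.tsv"
        cname = f"{cond.name}_paircorr.tsv"
        if store.fresh(rname, ihash) and store.fresh(cname, ihash):
            store.reuse("correlate", rname, cname)
            continue
        series = InteractionEnergySeries.load(src)
        retained = cn.filter_by_mean_energy(series, thr.mean_energy_kjmol)
        C = cn.pair_correlations(series, retained, thr.correlation)
        rdf = pd.DataFrame(
            {
                "chain_i": [p[0][0] for p in retained.pairs],
                "res_i": [p[0][1] for p in retained.pairs],
                "chain_j": [p[1][0] for p in retained.pairs],
                "res_j": [p[1][1] for p in retained.pairs],
                "mean_energy": retained.mean_energies,
            }
        )
        rdf.to_csv(store.path(rname), sep="\t", index=False, float_format="%.10g")
        coo = C.matrix.tocoo()
        cdf = pd.DataFrame({"m": coo.row, "n": coo.col, "c": coo.data})
        cdf = cdf.sort_values(["m", "n"]).reset_index(drop=True)
        cdf.to_csv(store.path(cname), sep="\t", index=False, float_format="%.12g")
        params = {"condition": cond.name, "mean_energy": thr.mean_energy_kjmol,
                  "correlation": thr.correlation}
        store.record("correlate", rname, ihash, params)
        store.record("correlate", cname, ihash, params)


def _load_correlation(store: _Store, stage: str, cond_name: str):
    import scipy.sparse as sp

    rp = store.require(stage, f"{cond_name}_retained.tsv")
    cp = store.require(stage, f"{cond_name}_paircorr.tsv")
    rdf = pd.read_csv(rp, sep="\t")
    pairs = [
        ((str(r.chain_i), int(r.res_i)), (str(r.chain_j), int(r.res_j)))
        for r in rdf.itertuples()
    ]
    retained = cn.RetainedPairSet(
        pairs=pairs,
        mean_energies=rdf.mean_energy.to_numpy(),
        indices=np.arange(len(pairs)),
        threshold=float("nan"),
    )
    cdf = pd.read_csv(cp, sep="\t")
    P = len(pairs)
    mat = sp.csr_matrix(
        (cdf.c.to_numpy(), (cdf.m.to_numpy(), cdf.n.to_numpy())), shape=(P, P)
    )
    return retained, cn.PairCorrelationMatrix(pairs=pairs, matrix=mat, c_min=float("nan"))


def _residue_universe(config: RunConfig, store: _Store) -> list | None:
    """Common residue label set across conditions so matrices are congruent."""
    labels: set = set()
    for cond in config.conditions:
        rp = store.path(f"{cond.name}_retained.tsv")
        if not rp.exists():
            return None
        rdf = pd.read_csv(rp, sep="\t")
        for r in rdf.itertuples():
            labels.add((str(r.chain_i), int(r.res_i)))
            labels.add((str(r.chain_j), int(r.res_j)))
    return sorted(labels)


def _stage_project(config: RunConfig, store: _Store) -> None:
    labels = _residue_universe(config, store)
    if labels is None:
        raise DependencyError(
            "stage 'project' requires correlate artifacts for every condition"
        )
    for cond in config.conditions:
        rp = store.require("project", f"{cond.name}_retained.tsv")
        cp = store.require("project", f"{cond.name}_paircorr.tsv")
        name = f"{cond.name}_R.tsv"
        ihash = _hash_bytes(_file_hash(rp), _file_hash(cp), _params_hash(labels))
        if store.fresh(name, ihash):
            store.reuse("project", name)
            continue
        retained, C = _load_correlation(store, "project", cond.name)
        R = cn.project_to_residues(C, retained, residue_labels=labels)
        R.save(store.path(name))
        store.record("project", name, ihash, {"condition": cond.name})


def _stage_consensus(config: RunConfig, store: _Store) -> None:
    paths = [store.require("consensus", f"{c.name}_R.tsv") for c in config.conditions]
    ihash = _hash_bytes(*[_file_hash(p) for p in paths])
    if store.fresh("consensus_R.tsv", ihash):
        store.reuse("consensus", "consensus_R.tsv")
    else:
        mats = [cn.ResidueCorrelationMatrix.load(p) for p in paths]
        cn.consensus_rms(mats).save(store.path("consensus_R.tsv"))
        store.record("consensus", "consensus_R.tsv", ihash,
                     {"conditions": [c.name for c in config.conditions]})
    ref = config.reference()
    bound = [c.name for c in config.conditions if c.name != ref]
    if bound and store.fresh("difference_R.tsv", ihash):
        store.reuse("consensus", "difference_R.tsv")
    elif bound:
        free = cn.ResidueCorrelationMatrix.load(store.path(f"{ref}_R.tsv"))
        mats = [
            cn.ResidueCorrelationMatrix.load(store.path(f"{b}_R.tsv")) for b in bound
        ]
        cn.difference_rms(mats, free).save(store.path("difference_R.tsv"))
        store.record("consensus", "difference_R.tsv", ihash,
                     {"reference": ref, "bound": bound})


def _stage_hotspots(config: RunConfig, store: _Store) -> None:
    src = store.require("hotspots", "consensus_R.tsv")
    thr = config.thresholds
    ihash = _hash_bytes(_file_hash(src), _params_hash({"pct": thr.hotspot_percentile}))
    if store.fresh("hotspots.tsv", ihash) and store.fresh("scores.tsv", ihash):
        store.reuse("hotspots", "scores.tsv", "hotspots.tsv")
        return
    R = cn.ResidueCorrelationMatrix.load(src)
    scores = cn.residue_scores(R)
    scores.save(store.path("scores.tsv"))
    hot = cn.select_hotspots(scores, thr.hotspot_percentile)
    hot.save(store.path("hotspots.tsv"))
    store.record("hotspots", "scores.tsv", ihash, {})
    store.record("hotspots", "hotspots.tsv", ihash,
                 {"percentile": thr.hotspot_percentile, "cut": hot.cut_value})


def _stage_cluster(config: RunConfig, store: _Store) -> None:
    src = store.require("cluster", "consensus_R.tsv")
    thr = config.thresholds
    ihash = _hash_bytes(_file_hash(src), _params_hash({"k": thr.n_clusters}))
    if store.fresh("clusters.tsv", ihash):
        store.reuse("cluster", "clusters.tsv")
        return
    R = cn.ResidueCorrelationMatrix.load(src)
    D = cn.row_distance_matrix(R)
    tree = cn.divisive_cluster(D, n_clusters=min(thr.n_clusters, D.shape[0]))
    tree.save(store.path("clusters.tsv"), labels=[f"{c}:{i}" for c, i in R.labels])
    store.record("cluster", "clusters.tsv", ihash, {"n_clusters": thr.n_clusters})


def _stage_occupancy(config: RunConfig, store: _Store) -> None:
    for cond in config.conditions:
        sel = _selection_for(config, cond)
        if not sel.ligand_chain_ids:
            continue
        topo, traj = _load_condition_system(config, cond, store)
        if not any(b.chain_id in set(sel.ligand_chain_ids) for b in topo.beads):
            continue  # condition has no ligand (e.g. the free state)
        name = f"{cond.name}_occupancy.tsv"
        ihash = _hash_bytes(
            _params_hash({"cond": cond.name, "cutoff": config.thresholds.occupancy_cutoff_nm})
        )
        prof = sg.ligand_occupancy(
            traj, topo, sel, cutoff=config.thresholds.occupancy_cutoff_nm
        )
        prof.save(store.path(name))
        store.record("occupancy", name, ihash, {"condition": cond.name})


def _tilt_results(config: RunConfig, cond: ConditionConfig, store: _Store) -> sg.TiltResults:
    topo, traj = _load_condition_system(config, cond, store)
    sel = _selection_for(config, cond)
    return sg.TiltAnalysis(traj, topo, sel).fit()


def _stage_tilt(config: RunConfig, store: _Store) -> None:
    ref_name = config.reference()
    results = {c.name: _tilt_results(config, c, store) for c in config.conditions}
    ref_summary = results[ref_name].summary()
    for cond in config.conditions:
        name = f"{cond.name}_tilt.tsv"
        summ = (
            results[cond.name].summary()
            if cond.name == ref_name
            else results[cond.name].summary(reference=ref_summary)
        )
        summ.save(store.path(name))
        store.record("tilt", name, _hash_bytes(_params_hash({"cond": cond.name})),
                     {"condition": cond.name, "reference": ref_name})


def _stage_compare(config: RunConfig, store: _Store) -> None:
    ref_name = config.reference()
    ref_cond = config.condition(ref_name)
    ref_res = _tilt_results(config, ref_cond, store)
    for cond in config.conditions:
        if cond.name == ref_name:
            continue
        res = _tilt_results(config, cond, store)
        df = res.compare(ref_res, decorrelate_stride=config.stride)
        name = f"compare_{cond.name}.tsv"
        df.to_csv(store.path(name), sep="\t", index=False, float_format="%.10g")
        store.record("compare", name, _hash_bytes(_params_hash({"cond": cond.name})),
                     {"condition": cond.name, "reference": ref_name})


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "energies": _stage_energies,
    "correlate": _stage_correlate,
    "project": _stage_project,
    "consensus": _stage_consensus,
    "hotspots": _stage_hotspots,
    "cluster": _stage_cluster,
    "occupancy": _stage_occupancy,
    "tilt": _stage_tilt,
    "compare": _stage_compare,
}


def run_pipeline(config: RunConfig, stages=None) -> dict:
    """Run the requested stages (in canonical order) and return the run report."""
    config.validate()
    requested = list(STAGES) if stages is None else [s for s in STAGES if s in set(stages)]
    unknown = set(stages or []) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    store = _Store(Path(config.output_dir), config.seed)
    log_file = store.path("run.log")
    handler = logging.FileHandler(log_file)
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        for stage in requested:
            logger.info("stage=%s start", stage)
            _STAGE_FUNCS[stage](config, store)
    finally:
        logger.removeHandler(handler)
        handler.close()
    report = {
        "seed": config.seed,
        "stride": config.stride,
        "thresholds": dataclasses.asdict(config.thresholds),
        "stages": requested,
        "artifacts": store.produced,
        "conditions": [c.name for c in config.conditions],
    }
    store.path("run_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
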