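"""End-to-end junction analysis pipeline.

Orchestrates: conformational sampling for every (sequence, stage,
replicate) -> H-bond / conformer analysis -> distance-matrix PCA ->
conductance-trace generation -> clustering & heterogeneity -> pathway
comparison, and writes a machine-readable summary JSON.  Deterministic
given the global seed: per-task seeds are derived with
numpy.random.SeedSequence(global_seed, spawn_key=(module_index, ...)),
with module indices documented in ``SEED_DOMAINS``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import distance_pca, hbond_conformers, pathway_transport, \
    trace_clustering
from .gold_restraints import RestraintParams
from .synthetic_data import (
    Ensemble,
    SamplerConfig,
    TraceGenConfig,
    generate_traces,
    sample_ensemble,
    traces_to_dataframe,
)

__all__ = ["PipelineConfig", "run_pipeline", "plan_accounting",
           "derive_seed"]

logger = logging.getLogger(__name__)

#: The ten study peptides: methionine-anchored tetra- and pentapeptides
#: with aliphatic (G, A), aromatic (Y, W) and constrained (P) cores.
STUDY_SEQUENCES = ["MGGM", "MAAM", "MYYM", "MWWM", "MPPM",
                   "MGGGM", "MAAAM", "MYYYM", "MWWWM", "MPPPM"]

#: Fixed spawn-key domains for per-module seed derivation.
SEED_DOMAINS = {"sampler": 1, "traces": 2, "clustering": 3}


def derive_seed(global_seed: int, domain: str, *indices: int) -> int:
    """Deterministic per-task seed below 2**31."""
    ss = np.random.SeedSequence(
        entropy=int(global_seed),
        spawn_key=(SEED_DOMAINS[domain], *indices))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


@dataclass
class PipelineConfig:
    """Full pipeline configuration (YAML/JSON round-trippable)."""

    sequences: list[str] = field(
        default_factory=lambda: list(STUDY_SEQUENCES))
    stages: list[float] = field(default_factory=lambda: [6.0, 9.0, 12.0])
    replicates: int = 16
    nominal_replicate_ns: float = 200.0
    seed: int = 0
    outdir: str = "pepjunction_out"
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    restraints: RestraintParams = field(default_factory=RestraintParams)
    traces: TraceGenConfig = field(default_factory=TraceGenConfig)
    k_range: list[int] = field(default_factory=lambda: [2, 3, 4, 5, 6])
    hbond_threshold: float = 3.0
    pathway_eps_c: float = pathway_transport.DEFAULT_EPS_C
    write_traces_csv: bool = False

    def validate(self) -> None:
        if self.replicates < 0:
            raise ValueError("replicates must be >= 0")
        if any(s <= 0 for s in self.stages):
            raise ValueError("stages must be positive")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["restraints"].pop("charges", None)
        # YAML has no tuple type; keep the dict YAML-stable
        d["sampler"]["temperature_ladder"] = list(
            d["sampler"]["temperature_ladder"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "sampler" in d and isinstance(d["sampler"], dict):
            d["sampler"] = SamplerConfig(**d["sampler"])
        if "restraints" in d and isinstance(d["restraints"], dict):
            d["restraints"] = RestraintParams(**d["restraints"])
        if "traces" in d and isinstance(d["traces"], dict):
            d["traces"] = TraceGenConfig(**d["traces"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML superset covers JSON
        return cls.from_dict(data)

    @classmethod
    def quick(cls, seed: int = 0, outdir: str = "pepjunction_out",
              **overrides) -> "PipelineConfig":
        """Reduced-scale preset: 2 sequences x 2 stages x 2 replicates,
        short chains, fewer traces."""
        cfg = cls(
            sequences=["MAAM", "MGGGM"],
            stages=[6.0, 12.0],
            replicates=2,
            seed=seed,
            outdir=outdir,
            sampler=SamplerConfig(n_steps=5000, burn_in=2000, thin=10),
            traces=TraceGenConfig(n_traces=400),
            **overrides,
        )
        return cfg


def plan_accounting(config: PipelineConfig) -> dict:
    """Simulation-plan totals: number of (sequence, stage, replicate)
    simulations and the nominal MD-equivalent time they stand in for."""
    n_sim = len(config.sequences) * len(config.stages) * config.replicates
    total_ns = n_sim * config.nominal_replicate_ns
    return {
        "n_simulations": n_sim,
        "total_sampled_steps": n_sim * config.sampler.n_steps,
        "nominal_time_ns": total_ns,
        "nominal_time_us": total_ns / 1000.0,
    }


def _stage_key(stage: float) -> str:
    return f"{stage:g}"


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the summary dict (also written to
    ``<outdir>/summary.json``).  Idempotent given the config seed."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": config.to_dict(), "files": {}}
    t_start = time.time()

    # --- 1. sampling -----------------------------------------------------
    logger.info("sampling %d sequences x %d stages x %d replicates",
                len(config.sequences), len(config.stages),
                config.replicates)
    ensembles: dict[tuple[str, float], list[Ensemble]] = {}
    for si, seq in enumerate(config.sequences):
        for ti, stage in enumerate(config.stages):
            reps = []
            for r in range(config.replicates):
                seed = derive_seed(config.seed, "sampler", si, ti, r)
                reps.append(sample_ensemble(seq, stage, config.sampler,
                                            config.restraints, seed))
            ensembles[(seq, stage)] = reps
    logger.info("sampling done in %.1fs", time.time() - t_start)

    def merged(seq: str, stage: float) -> Ensemble:
        reps = ensembles[(seq, stage)]
        return Ensemble(
            sequence=seq, stage=stage, replicate_seed=-1,
            topology=reps[0].topology,
            frames=np.concatenate([e.frames for e in reps]),
            energies=np.concatenate([e.energies for e in reps]),
            acceptance_rate=float(np.mean(
                [e.acceptance_rate for e in reps])))

    # --- 2. H-bond analysis and conformer selection ----------------------
    t0 = time.time()
    hbond_block: dict = {}
    selected: dict[str, dict] = {}
    for seq in config.sequences:
        per_stage = {}
        for stage in config.stages:
            ens = merged(seq, stage)
            series = hbond_conformers.hbond_distance_series(ens)
            per_stage[_stage_key(stage)] = {
                "fraction_below_cutoff": hbond_conformers.hbond_fraction(ens),
                "mean_distance_A": float(series.distances.mean()),
                "orientation_orthogonal_fraction":
                    hbond_conformers.junction_orientation_analysis(
                        ens)["orthogonal_fraction"],
            }
        hbond_block[seq] = per_stage
        # turn conformer from the shortest stage, extended from the longest
        lo, hi = min(config.stages), max(config.stages)
        ens_lo, ens_hi = merged(seq, lo), merged(seq, hi)
        sel_lo = hbond_conformers.select_conformer(
            ens_lo, hbond_conformers.hbond_distance_series(ens_lo))
        sel_hi = hbond_conformers.select_conformer(
            ens_hi, hbond_conformers.hbond_distance_series(ens_hi))
        selected[seq] = {
            "turn": {"stage": lo, "frame": sel_lo.frame_index,
                     "hbond_distance_A": sel_lo.distance,
                     "ensemble": ens_lo},
            "extended": {"stage": hi, "frame": sel_hi.frame_index,
                         "hbond_distance_A": sel_hi.distance,
                         "ensemble": ens_hi},
        }
    summary["hbond"] = hbond_block
    summary["selected_conformers"] = {
        seq: {k: {kk: vv for kk, vv in v.items() if kk != "ensemble"}
              for k, v in sel.items()}
        for seq, sel in selected.items()}
    logger.info("hbond analysis done in %.1fs", time.time() - t0)

    # --- 3. distance-matrix PCA (per peptide length) ---------------------
    t0 = time.time()
    pca_block = {}
    by_len: dict[int, list[Ensemble]] = {}
    for (seq, stage) in ensembles:
        by_len.setdefault(len(seq), []).append(merged(seq, stage))
    for n_res, group in sorted(by_len.items()):
        feats = distance_pca.featurize(group)
        model = distance_pca.fit_whitened_pca(feats, n_components=2)
        proj = distance_pca.project(model, feats)
        depop = distance_pca.depopulation_metric(
            proj, threshold=config.hbond_threshold,
            stages=sorted(config.stages))
        pca_block[str(n_res)] = {
            "n_features": len(feats.columns),
            "explained_variance_ratio":
                model.explained_variance_ratio.tolist(),
            "depopulation_by_stage": {
                _stage_key(s): v for s, v in depop.items()},
        }
    summary["pca"] = pca_block
    logger.info("PCA done in %.1fs", time.time() - t0)

    # --- 4. conductance traces and clustering ----------------------------
    t0 = time.time()
    trace_cfg = dataclasses.replace(
        config.traces, seed=derive_seed(config.seed, "traces"))
    traces = generate_traces(trace_cfg)
    feats = trace_clustering.trace_features(traces)
    counts, edges, overflow = trace_clustering.histogram_1d(traces)
    peaks = trace_clustering.fit_lorentzian_peaks(counts, edges, n_peaks=2)
    cl_seed = derive_seed(config.seed, "clustering")
    k, sil = trace_clustering.silhouette_select_k(
        feats, range(config.k_range[0], config.k_range[-1] + 1), cl_seed)
    result = trace_clustering.gmm_cluster(
        feats, k, cl_seed, traces=traces, peak_levels=peaks.centers[:2])
    het = trace_clustering.heterogeneity_classification(
        traces, result.assignments, peaks.centers[:2])
    mol_share = float(np.mean(
        result.assignments == result.molecular_cluster)) \
        if result.molecular_cluster is not None else None
    summary["traces"] = {
        "n_traces": len(traces),
        "peak_centers_logg": peaks.centers.tolist(),
        "peak_fit_converged": peaks.converged,
        "chosen_k": k,
        "silhouette_by_k": {str(kk): v for kk, v in sil.items()},
        "cluster_shares": result.cluster_shares.tolist(),
        "molecular_cluster": result.molecular_cluster,
        "molecular_share": mol_share,
        "heterogeneity_verdict": het["verdict"],
    }
    if config.write_traces_csv:
        path = outdir / "traces.csv"
        traces_to_dataframe(traces).to_csv(path, index=False)
        summary["files"]["traces_csv"] = path.name
    logger.info("trace clustering done in %.1fs", time.time() - t0)

    # --- 5. pathway comparison -------------------------------------------
    t0 = time.time()
    pathway_block = {}
    for seq, sel in selected.items():
        turn = sel["turn"]["ensemble"].conformation(sel["turn"]["frame"])
        ext = sel["extended"]["ensemble"].conformation(
            sel["extended"]["frame"])
        try:
            cmp = pathway_transport.compare_conformers(
                turn, ext, eps_c=config.pathway_eps_c)
            pathway_block[seq] = {
                "L_turn": cmp["turn"].effective_length,
                "L_extended": cmp["extended"].effective_length,
                "L_turn_through_bond":
                    cmp["turn_through_bond"].effective_length,
                "n_hydrogen_turn": cmp["turn"].n_hydrogen,
                "decay_ratio": cmp["decay_ratio"],
                "turn_hbond_advantage": cmp["turn_hbond_advantage"],
            }
        except ValueError as exc:
            pathway_block[seq] = {"error": str(exc)}
    summary["pathway"] = pathway_block
    logger.info("pathway analysis done in %.1fs", time.time() - t0)

    summary["plan"] = plan_accounting(config)
    path = outdir / "summary.json"
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    summary["files"]["summary_json"] = path.name
    logger.info("pipeline complete in %.1fs", time.time() - t_start)
    return summary
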