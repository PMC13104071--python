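"""End-to-end pipeline: simulate/load -> rarefy -> diversity -> assembly ->
stability -> networks -> gradient, driven by one config with a manifest.

Every stochastic stage's seed is derived from the master seed, so a rerun
with the same config reproduces all outputs; stage outputs are checksummed
and a stage is skipped on rerun when its recorded checksums still match.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assembly import fit_neutral_model, modified_mantel, niche_overlap, stochasticity_by_group
from .datamodel import SampleFrame
from .diversity import (
    bray_curtis_matrix, group_dispersion, pcoa, permanova, richness, shannon,
)
from .gradient import (
    compare_groups, compute_pdi, pocd_percent_change, species_trends,
    stability_pocd_association,
)
from .io import (
    read_community_table, read_sample_frame, write_community_table,
    write_sample_frame,
)
from .networks import (
    align_samples_by_depth, build_network, core_edge_analytics,
    natural_connectivity, robustness_curve, sparcc_correlations,
    sparcc_pvalues, topology,
)
from .preprocess import filter_taxa_by_mean_abundance, rarefy
from .simulate import SimulationConfig, simulate_dataset
from .stability import avd_stability, identify_core_taxa, stability_drivers

log = logging.getLogger("permacomm.pipeline")

STAGES = ("simulate", "rarefy", "diversity", "assembly", "stability",
          "networks", "gradient")


@dataclasses.dataclass
class PipelineConfig:
    """Everything one run needs; loads from / round-trips to YAML."""

    outdir: str = "permacomm_out"
    seed: int = 0
    table_path: str | None = None
    metadata_path: str | None = None
    simulate: dict | None = None          # SimulationConfig overrides
    rarefaction: str = "min"              # "min" or an integer depth
    grouping: str = "main_layer"
    n_permutations: int = 999
    n_null: int = 200
    sparcc_n_boot: int = 99
    network_top_taxa: int = 80
    network_r_min: float = 0.35
    network_p_max: float = 0.05
    mantel_variables: tuple = ("depth_m", "Tp", "PWC", "pH", "POM", "TN")
    trend_gradient: str = "site"
    association_stratum: str = "sub_layer"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["mantel_variables"] = list(d["mantel_variables"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    def validate(self, frame: SampleFrame | None = None) -> None:
        if self.simulate is None and (self.table_path is None or self.metadata_path is None):
            raise ValueError("config needs either a simulate block or input paths")
        if frame is not None:
            cols = set(frame.data.columns)
            for c in (self.grouping, self.trend_gradient, self.association_stratum):
                if c not in cols:
                    raise ValueError(f"grouping column {c!r} not in metadata")

    def stage_seed(self, stage: str) -> int:
        return int(
            np.random.SeedSequence([self.seed, STAGES.index(stage)])
            .generate_state(1)[0] % (2 ** 31)
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class RunManifest:
    def __init__(self, config: PipelineConfig):
        self.data = {
            "version": __version__,
            "config": dataclasses.asdict(config),
            "stages": {},
            "warnings": [],
        }
        self.data["config"]["mantel_variables"] = list(config.mantel_variables)

    def record(self, stage: str, outputs: list[Path], skipped: bool = False):
        self.data["stages"][stage] = {
            "skipped": skipped,
            "outputs": {p.name: _sha256(p) for p in outputs},
        }

    def record_error(self, stage: str, error: Exception):
        self.data["stages"][stage] = {"error": f"{type(error).__name__}: {error}"}

    def add_warnings(self, stage: str, caught):
        for w in caught:
            self.data["warnings"].append({"stage": stage, "message": str(w.message)})

    def write(self, path: Path):
        path.write_text(json.dumps(self.data, indent=2, default=str))


def _stage_current(manifest_path: Path, stage: str, outputs: list[Path]) -> bool:
    """True when a previous manifest recorded these outputs and they verify."""
    if not manifest_path.exists():
        return False
    try:
        prev = json.loads(manifest_path.read_text())
    except json.JSONDecodeError:
        return False
    rec = prev.get("stages", {}).get(stage)
    if not rec or "outputs" not in rec or rec.get("error"):
        return False
    for p in outputs:
        if not p.exists() or rec["outputs"].get(p.name) != _sha256(p):
            return False
    return True


def run_pipeline(config: PipelineConfig, resume: bool = True) -> RunManifest:
    """Execute all stages in order; returns the written manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    manifest = RunManifest(config)
    config.to_yaml(outdir / "config.yaml")

    state: dict = {}
    failed = False
    for stage in STAGES:
        if failed:
            manifest.data["stages"][stage] = {"skipped": True, "reason": "upstream failure"}
            continue
        fn = globals()[f"_stage_{stage}"]
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                outputs = fn(config, outdir, state,
                             resume and _prev_ok(manifest_path, stage))
            manifest.add_warnings(stage, caught)
            manifest.record(stage, outputs)
            log.info("stage %s done (%d outputs)", stage, len(outputs))
        except Exception as exc:           # noqa: BLE001 - recorded, not hidden
            log.error("stage %s failed: %s", stage, exc)
            manifest.record_error(stage, exc)
            failed = True
    manifest.write(manifest_path)
    return manifest


def _prev_ok(manifest_path, stage):
    # closure helper so stages can decide to reuse on-disk outputs
    def check(outputs):
        return _stage_current(manifest_path, stage, outputs)
    return check


# --------------------------------------------------------------------------
# stages: each returns the list of files it produced
# --------------------------------------------------------------------------

def _stage_simulate(config, outdir, state, prev_ok):
    table_p = outdir / "table.tsv"
    meta_p = outdir / "metadata.tsv"
    truth_p = outdir / "truth.json"
    if config.simulate is not None and prev_ok([table_p, meta_p, truth_p]):
        state["table"], _ = read_community_table(table_p, drop_zero=False)
        state["frame"] = read_sample_frame(meta_p)
        return [table_p, meta_p, truth_p]
    if config.simulate is not None:
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("seed", config.stage_seed("simulate"))
        sim = SimulationConfig(**sim_kwargs)
        ds = simulate_dataset(sim)
        config.validate(ds.frame)
        write_community_table(ds.table, table_p)
        write_sample_frame(ds.frame, meta_p)
        truth = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in ds.truth.items()
        }
        truth_p.write_text(json.dumps(truth, indent=2))
        state["table"], state["frame"] = ds.table, ds.frame
        return [table_p, meta_p, truth_p]
    table, _ = read_community_table(config.table_path)
    frame = read_sample_frame(config.metadata_path)
    config.validate(frame)
    frame = frame.aligned_to(table.sample_ids)
    state["table"], state["frame"] = table, frame
    write_community_table(table, table_p)
    write_sample_frame(frame, meta_p)
    return [table_p, meta_p]


def _stage_rarefy(config, outdir, state, prev_ok):
    out = outdir / "rarefied.tsv"
    if prev_ok([out]):
        state["rarefied"], _ = read_community_table(out, drop_zero=False)
        return [out]
    depth = (
        int(state["table"].sample_sums().min())
        if config.rarefaction == "min" else int(config.rarefaction)
    )
    rtab = rarefy(state["table"], depth, seed=config.stage_seed("rarefy"))
    rtab, _ = rtab.drop_zero_taxa()
    state["rarefied"] = rtab
    write_community_table(rtab, out)
    return [out]


def _stage_diversity(config, outdir, state, prev_ok):
    table = state["rarefied"]
    frame = state["frame"].aligned_to(table.sample_ids)
    groups = frame.column(config.grouping)
    alpha = pd.DataFrame({
        "sample_id": table.sample_ids,
        "richness": richness(table),
        "shannon": shannon(table),
        "group": groups,
    })
    dm = bray_curtis_matrix(table)
    state["braycurtis"] = dm
    ord_res = pcoa(dm)
    coords = pd.DataFrame(
        ord_res.coordinates[:, :2], columns=["PCo1", "PCo2"])
    coords.insert(0, "sample_id", table.sample_ids)
    perm = permanova(dm, groups, n_perm=config.n_permutations,
                     seed=config.stage_seed("diversity"))
    disp = group_dispersion(dm, groups)
    alpha["dispersion"] = disp
    summary = pd.DataFrame([{
        "grouping": config.grouping, "pseudo_F": perm.pseudo_F,
        "R2": perm.R2, "p": perm.p_value, "n_perm": perm.n_permutations,
        "pco1_prop": ord_res.proportion_explained[0],
    }])
    paths = [outdir / "alpha_diversity.tsv", outdir / "pcoa.tsv",
             outdir / "permanova.tsv"]
    alpha.to_csv(paths[0], sep="\t", index=False)
    coords.to_csv(paths[1], sep="\t", index=False)
    summary.to_csv(paths[2], sep="\t", index=False)
    return paths


def _stage_assembly(config, outdir, state, prev_ok):
    table = state["rarefied"]
    frame = state["frame"].aligned_to(table.sample_ids)
    groups = frame.column(config.grouping)
    seed = config.stage_seed("assembly")
    st = stochasticity_by_group(table, groups, n_null=config.n_null, seed=seed)
    st_df = pd.DataFrame([
        {"group": g, "mean_stochasticity_ratio": r.mean_ratio,
         "n_pairs": len(r.pair_ratios), "n_null": r.n_null}
        for g, r in st.items()
    ])
    state["stochasticity"] = st
    ncm_rows = []
    for lab in np.unique(groups):
        sub = table.select_samples(
            [s for s, g in zip(table.sample_ids, groups) if g == lab])
        sub, _ = sub.drop_zero_taxa()
        fit = fit_neutral_model(sub)
        ncm_rows.append({"group": lab, "Nm": fit.Nm, "m": fit.m, "R2": fit.R2,
                         "m_exceeds_one": fit.m_exceeds_one})
    ncm_df = pd.DataFrame(ncm_rows)
    overlap = pd.DataFrame([{"mean_levins_overlap": niche_overlap(
        filter_taxa_by_mean_abundance(table, 1e-3))}])
    dm = state.get("braycurtis") or bray_curtis_matrix(table)
    mantel_rows = []
    rng = np.random.default_rng(seed + 1)
    for var in config.mantel_variables:
        if var not in frame.data.columns:
            continue
        fit = modified_mantel(dm, frame.column(var).astype(float),
                              n_perm=min(config.n_permutations, 499),
                              seed=int(rng.integers(2 ** 31)))
        mantel_rows.append({"variable": var, "model": fit.model,
                            "r": fit.r, "p": fit.p})
    paths = [outdir / "stochasticity.tsv", outdir / "neutral_model.tsv",
             outdir / "niche_overlap.tsv", outdir / "mantel.tsv"]
    st_df.to_csv(paths[0], sep="\t", index=False)
    ncm_df.to_csv(paths[1], sep="\t", index=False)
    overlap.to_csv(paths[2], sep="\t", index=False)
    pd.DataFrame(mantel_rows).to_csv(paths[3], sep="\t", index=False)
    return paths


def _stage_stability(config, outdir, state, prev_ok):
    table = state["rarefied"]
    frame = state["frame"].aligned_to(table.sample_ids)
    groups = frame.column(config.grouping)
    core = identify_core_taxa(table)
    state["core"] = core
    profile = avd_stability(table, groups)
    state["stability"] = profile
    core_df = pd.DataFrame({
        "taxon_id": core.taxon_ids,
        "mean_rel_abundance": core.mean_rel_abundance.values,
        "occupancy": core.occupancy.values,
    })
    stab_df = pd.DataFrame({
        "sample_id": profile.sample_ids, "avd": profile.avd,
        "stability": profile.stability, "group": profile.groups,
        "standardization": profile.standardization,
    })
    from .preprocess import relative_abundance
    rel = relative_abundance(table)
    core_mask = np.isin(table.taxon_ids, core.taxon_ids)
    predictors = pd.DataFrame({
        "richness": richness(table),
        "core_abundance": rel[core_mask].sum(axis=0),
    }, index=table.sample_ids)
    drivers = stability_drivers(profile, predictors, strata=groups)
    paths = [outdir / "core_taxa.tsv", outdir / "stability.tsv",
             outdir / "stability_drivers.tsv"]
    core_df.to_csv(paths[0], sep="\t", index=False)
    stab_df.to_csv(paths[1], sep="\t", index=False)
    drivers.to_csv(paths[2], sep="\t", index=False)
    return paths


def _stage_networks(config, outdir, state, prev_ok):
    table = state["rarefied"]
    frame = state["frame"].aligned_to(table.sample_ids)
    groups = frame.column(config.grouping)
    depths = frame.column("depth_m").astype(float)
    seed = config.stage_seed("networks")
    tables = {}
    dd = {}
    for lab in np.unique(groups):
        m = groups == lab
        ids = [s for s, ok in zip(table.sample_ids, m) if ok]
        tables[lab] = table.select_samples(ids)
        dd[lab] = depths[m]
    aligned, _ = align_samples_by_depth(tables, dd)
    core = state.get("core")
    core_ids = set(core.taxon_ids) if core else set()
    rng = np.random.default_rng(seed)
    topo_rows, edge_frames, robust_frames = [], [], []
    for lab, sub in aligned.items():
        sub = filter_taxa_by_mean_abundance(sub, 1e-4)
        keep = np.argsort(sub.counts.sum(axis=1))[::-1][:config.network_top_taxa]
        sub = sub.select_taxa(np.sort(keep))
        rho = sparcc_correlations(sub, seed=int(rng.integers(2 ** 31)))
        pmat = sparcc_pvalues(sub, rho, n_boot=config.sparcc_n_boot,
                              seed=int(rng.integers(2 ** 31)))
        phylum = dict(zip(sub.taxon_ids, sub.lineage_rank("p__")))
        net = build_network(
            rho, pmat, sub.taxon_ids, r_min=config.network_r_min,
            p_max=config.network_p_max, phylum=phylum, core_ids=core_ids,
            group_id=str(lab), n_samples=sub.n_samples,
        )
        ts = topology(net)
        row = {"group": lab, **dataclasses.asdict(ts),
               "natural_connectivity": (natural_connectivity(net)
                                        if net.n_nodes else 0.0)}
        analytics = core_edge_analytics(net)
        row["core_core_edges"] = analytics.block_counts.get(("core", "core"), 0)
        row["core_other_edges"] = analytics.block_counts.get(("core", "other"), 0)
        row["mean_core_path_length"] = analytics.mean_core_path_length
        topo_rows.append(row)
        for u, v, d in net.graph.edges(data=True):
            edge_frames.append({"group": lab, "source": u, "target": v,
                                "rho": d["rho"], "p": d["p"], "sign": d["sign"]})
        if net.n_edges > 0:
            rc = robustness_curve(net, n_rep=20,
                                  seed=int(rng.integers(2 ** 31)))
            for f, nc, ncn in zip(rc.fractions, rc.nc_mean, rc.nc_normalized):
                robust_frames.append({"group": lab, "fraction": f,
                                      "nc": nc, "nc_normalized": ncn})
    paths = [outdir / "network_topology.tsv", outdir / "network_edges.tsv",
             outdir / "network_robustness.tsv"]
    pd.DataFrame(topo_rows).to_csv(paths[0], sep="\t", index=False)
    pd.DataFrame(edge_frames).to_csv(paths[1], sep="\t", index=False)
    pd.DataFrame(robust_frames).to_csv(paths[2], sep="\t", index=False)
    return paths


def _stage_gradient(config, outdir, state, prev_ok):
    table = state["rarefied"]
    frame = state["frame"].aligned_to(table.sample_ids)
    seed = config.stage_seed("gradient")
    site_table = (
        frame.data.groupby("site")[["ALT", "MAGT"]].mean().reset_index()
        if {"ALT", "MAGT"} <= set(frame.data.columns) else None
    )
    paths = []
    if site_table is not None and len(site_table) >= 3:
        pdi = compute_pdi(site_table)
        pdi_df = pd.DataFrame({"site": pdi.sites, "PDI": pdi.pdi})
        p = outdir / "pdi.tsv"
        pdi_df.to_csv(p, sep="\t", index=False)
        paths.append(p)
    trends = species_trends(table, frame.column(config.trend_gradient))
    p = outdir / "species_trends.tsv"
    trends.to_csv(p, sep="\t", index=False)
    paths.append(p)
    if "POCD" in frame.data.columns:
        pocd = frame.data.groupby(config.trend_gradient)["POCD"].mean()
        change = pocd_percent_change(pocd.to_numpy())
        ch_df = pd.DataFrame({
            "from": pocd.index[:-1], "to": pocd.index[1:],
            "percent_change": change,
        })
        comp = compare_groups(frame.column("POCD"),
                              frame.column(config.grouping))
        comp_df = pd.DataFrame({
            "group": list(comp.letters), "letter": list(comp.letters.values()),
        })
        comp_df["omnibus_p"] = comp.omnibus_p
        assoc = stability_pocd_association(
            state["stability"], frame, stratum=config.association_stratum,
            n_perm=min(config.n_permutations, 499), seed=seed,
        )
        assoc_df = pd.DataFrame([{
            "slope": assoc.slope, "partial_r": assoc.partial_r,
            "p": assoc.p, "stratum": config.association_stratum,
            "model": "fixed-effect stratum adjustment (mixed-model approximation)",
        }])
        for name, df in (("pocd_change.tsv", ch_df),
                         ("pocd_comparisons.tsv", comp_df),
                         ("stability_pocd.tsv", assoc_df)):
            p = outdir / name
            df.to_csv(p, sep="\t", index=False)
            paths.append(p)
    return paths
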