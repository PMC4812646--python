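"""Full-analysis orchestration: QC -> inbreeding -> ROH -> LD -> phase -> Ne.

Stages communicate through conventional file names inside one output
directory, so the CLI subcommands compose on each other's outputs and
``run_full`` is exactly the chain of the individual stages. All outputs are
TSV/JSON with fixed float formatting; given a fixed config and seed the
whole bundle is byte-stable across runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, defaults, ld_phase, ne, pedigree, qc, roh, synthetic
from .io_formats import (
    GenotypeDataset,
    plink_path,
    read_pedigree,
    read_plink_binary,
    read_plink_text,
    write_pedigree,
    write_plink_binary,
)

log = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"


class StageError(RuntimeError):
    """An analysis stage failed; the message names the stage."""


class ConfigError(ValueError):
    pass


DEFAULT_CONFIG = {
    "seed": 1,
    "populations": {},  # name -> {"plink_prefix": ..., "pedigree": ...(optional)}
    "simulate": None,   # optional SimConfig-style dict; generates the inputs
    "qc": {
        "sample_call_rate_min": defaults.SAMPLE_CALL_RATE_MIN,
        "het_sd": defaults.HET_SD,
        "dup_match_min": defaults.DUP_MATCH_MIN,
    },
    "roh": {
        "min_snps": defaults.ROH_MIN_SNPS,
        "min_length_kb": defaults.ROH_MIN_LENGTH_KB,
        "window": defaults.ROH_WINDOW,
        "max_het_per_window": defaults.ROH_MAX_HET_PER_WINDOW,
        "max_missing_per_window": defaults.ROH_MAX_MISSING_PER_WINDOW,
        "genome_length_kb": None,  # None -> sum of observed chromosome spans
        "consensus_incidence_min": 0.5,
    },
    "ld": {
        "max_dist_bp": defaults.LD_MAX_DIST_BP,
        "bin_bp": defaults.LD_BIN_BP,
        "thin_keep_every": defaults.THIN_KEEP_EVERY,
    },
    "ne": {
        "cm_per_mb": defaults.CM_PER_MB,
        "max_dist_bp": None,  # None -> all within-chromosome pairs
        "r2_offset": 0.0,     # optional sampling-inflation correction
    },
    "phase": {
        "headline_dist_bp": defaults.PHASE_HEADLINE_DIST_BP,
    },
}

SIM_KEYS = {
    "seed", "n_generations", "pop_size", "n_chromosomes", "chrom_length_morgan",
    "n_snps", "maf_range", "mating", "split", "missing_rate", "error_rate", "export",
}


def merge_config(user: dict) -> dict:
    """Deep-merge a user config over the defaults, rejecting unknown keys."""
    def merge(base, over, path):
        out = dict(base)
        for k, v in over.items():
            if k not in base and path in ("qc", "roh", "ld", "ne", "phase", ""):
                if path == "" and k not in DEFAULT_CONFIG:
                    raise ConfigError(f"unknown config key {k!r}")
                if path != "":
                    raise ConfigError(f"unknown config key {path}.{k}")
            if isinstance(v, dict) and isinstance(base.get(k), dict) and k != "populations":
                out[k] = merge(base[k], v, k)
            else:
                out[k] = v
        return out

    cfg = merge(DEFAULT_CONFIG, user or {}, "")
    if cfg["simulate"] is not None:
        unknown = set(cfg["simulate"]) - SIM_KEYS
        if unknown:
            raise ConfigError(f"unknown simulate keys {sorted(unknown)}")
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    return path


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def load_dataset(prefix: str | Path) -> GenotypeDataset:
    """Load a PLINK prefix, preferring the binary triplet over ped/map."""
    prefix = Path(prefix)
    if plink_path(prefix, ".bed").exists():
        return read_plink_binary(
            plink_path(prefix, ".bed"), plink_path(prefix, ".bim"), plink_path(prefix, ".fam")
        )
    if plink_path(prefix, ".ped").exists():
        return read_plink_text(plink_path(prefix, ".ped"), plink_path(prefix, ".map"))
    raise FileNotFoundError(f"no .bed or .ped found at prefix {prefix}")


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: dict, out: Path) -> dict:
    """Generate inputs with the Wright-Fisher simulator and register them."""
    sim = dict(cfg["simulate"])
    sim.setdefault("seed", cfg["seed"])
    if isinstance(sim.get("split"), (list, tuple, dict)):
        sp = sim["split"]
        sim["split"] = (
            synthetic.SplitSpec(generation=sp["generation"], sizes=tuple(sp["sizes"]))
            if isinstance(sp, dict)
            else synthetic.SplitSpec(generation=sp[0], sizes=tuple(sp[1]))
        )
    if isinstance(sim.get("maf_range"), list):
        sim["maf_range"] = tuple(sim["maf_range"])
    config = synthetic.SimConfig(**sim)
    ds, truth = synthetic.simulate(config)
    simdir = out / "sim"
    simdir.mkdir(parents=True, exist_ok=True)
    populations = {}
    labels = sorted(ds.samples["population"].unique())
    for label in labels:
        sub = ds.subset(sample_idx=np.flatnonzero(ds.samples["population"].to_numpy() == label))
        write_plink_binary(sub, simdir / label)
        populations[label] = {"plink_prefix": str(simdir / label), "pedigree": str(simdir / "pedigree.tsv")}
    write_pedigree(truth.pedigree, simdir / "pedigree.tsv")
    _write_tsv(synthetic.truth_autozygosity_frame(truth, list(ds.sample_ids)), simdir / "truth_autozygosity.tsv")
    cfg["populations"] = populations
    return {"populations": list(populations)}


def stage_qc(cfg: dict, out: Path) -> dict:
    """Run both QC profiles per population and write filtered datasets."""
    info = {}
    for pop, spec in cfg["populations"].items():
        ds = load_dataset(spec["plink_prefix"])
        s_rep = qc.sample_qc(
            ds,
            call_rate_min=cfg["qc"]["sample_call_rate_min"],
            het_sd=cfg["qc"]["het_sd"],
            dup_match_min=cfg["qc"]["dup_match_min"],
        )
        _write_tsv(s_rep.table, out / "qc" / f"{pop}.sample_qc.tsv")
        for profile_name in ("inbreeding", "ld"):
            profile = qc.PROFILES[profile_name]
            v_rep = qc.run_profile_snp_qc(ds, profile)
            _write_tsv(v_rep.table, out / "qc" / f"{pop}.{profile_name}.snp_qc.tsv")
            filtered, counts = qc.apply_qc(ds, s_rep, v_rep)
            _write_tsv(counts, out / "qc" / f"{pop}.{profile_name}.counts.tsv")
            write_plink_binary(filtered, out / "qc" / f"{pop}.{profile_name}")
            info[f"{pop}.{profile_name}"] = {
                "n_samples": filtered.n_samples,
                "n_snps": filtered.n_snps,
            }
    return info


def _qc_prefix(out: Path, pop: str, profile: str) -> Path:
    prefix = out / "qc" / f"{pop}.{profile}"
    if not plink_path(prefix, ".bed").exists():
        raise StageError(f"missing QC output for {pop!r} ({profile}); run `pigdiv qc` first")
    return prefix


def stage_inbreeding(cfg: dict, out: Path) -> dict:
    """F_x / F_ROH / F_SNP per population plus the estimator correlation matrix."""
    info = {}
    for pop, spec in cfg["populations"].items():
        ds = load_dataset(_qc_prefix(out, pop, "inbreeding"))
        vectors = {}
        if spec.get("pedigree"):
            ped = read_pedigree(spec["pedigree"])
            fx = pedigree.wright_inbreeding(ped)
            vectors["pedigree"] = fx
            depth = pedigree.pedigree_depth(ped)
            _write_tsv(depth, out / "inbreeding" / f"{pop}.pedigree_depth.tsv")
        segs = _detect(cfg, ds)
        genome_kb = _genome_length_kb(cfg, ds)
        vectors["roh"] = roh.f_roh(segs, list(ds.sample_ids), genome_kb)
        vectors["snp"] = roh.f_snp(ds)
        table = pd.DataFrame({"animal": [str(s) for s in ds.sample_ids]})
        for name, vec in vectors.items():
            table[f"F_{name}"] = table["animal"].map(vec.values)
        _write_tsv(table, out / "inbreeding" / f"{pop}.inbreeding.tsv")
        rows = []
        names = list(vectors)
        for a in names:
            for b in names:
                if a < b:
                    comp = pedigree.compare_inbreeding(vectors[a], vectors[b])
                    rows.append((a, b, comp.r if comp.r is not None else np.nan, comp.n, comp.reason))
        _write_tsv(
            pd.DataFrame(rows, columns=["method_a", "method_b", "pearson_r", "n", "reason"]),
            out / "inbreeding" / f"{pop}.correlations.tsv",
        )
        means = {f"mean_F_{k}": float(np.nanmean(list(v.values.values()))) for k, v in vectors.items()}
        info[pop] = means
    return info


def _detect(cfg: dict, ds: GenotypeDataset) -> list[roh.RohSegment]:
    r = cfg["roh"]
    return roh.detect_roh(
        ds,
        min_snps=r["min_snps"],
        min_length_kb=r["min_length_kb"],
        window=r["window"],
        max_het_per_window=r["max_het_per_window"],
        max_missing_per_window=r["max_missing_per_window"],
        autosomes=None,
    )


def _genome_length_kb(cfg: dict, ds: GenotypeDataset) -> float:
    fixed = cfg["roh"]["genome_length_kb"]
    if fixed is not None:
        return float(fixed)
    total = 0.0
    for _, sub in ds.snps.groupby("chromosome"):
        total += float(sub["position_bp"].max()) / 1000.0
    return total


def stage_roh(cfg: dict, out: Path) -> dict:
    """ROH segments, summary, within-population sharing and consensus regions."""
    info = {}
    segments_by_pop = {}
    sizes = {}
    for pop in cfg["populations"]:
        ds = load_dataset(_qc_prefix(out, pop, "inbreeding"))
        segs = _detect(cfg, ds)
        segments_by_pop[pop] = segs
        sizes[pop] = ds.n_samples
        _write_tsv(roh.segments_to_frame(segs), out / "roh" / f"{pop}.segments.tsv")
        summary = roh.summarize_roh(
            segs, list(ds.sample_ids), populations={str(s): pop for s in ds.sample_ids},
            genome_length_kb=_genome_length_kb(cfg, ds),
        )
        _write_tsv(summary["per_sample"], out / "roh" / f"{pop}.per_sample.tsv")
        _write_tsv(summary["per_population"], out / "roh" / f"{pop}.per_population.tsv")
        regions, table = roh.shared_roh({pop: segs}, sizes, mode="within", match="exact")
        _write_tsv(table, out / "roh" / f"{pop}.shared_within.tsv")
        cons = roh.consensus_regions(
            segs, ds, [str(s) for s in ds.sample_ids], cfg["roh"]["consensus_incidence_min"]
        )
        roh.regions_to_bed(cons, out / "roh" / f"{pop}.consensus.bed")
        info[pop] = {
            "n_segments": len(segs),
            "n_short": summary["n_segments_short"],
            "n_long": summary["n_segments_long"],
        }
    pops = list(cfg["populations"])
    if len(pops) == 2:
        regions, table = roh.shared_roh(
            segments_by_pop, sizes, mode="between", match="exact", populations=(pops[0], pops[1])
        )
        _write_tsv(table, out / "roh" / "shared_between.tsv")
        info["shared_between"] = int(table["n_shared_regions"].iloc[-1])
    return info


def stage_ld(cfg: dict, out: Path) -> dict:
    """LD decay, adjacent/thinned summaries and the pair table feeding Ne."""
    info = {}
    for pop in cfg["populations"]:
        ds = load_dataset(_qc_prefix(out, pop, "ld"))
        pairs = ld_phase.ld_pairs(ds, max_dist_bp=cfg["ne"]["max_dist_bp"])
        _write_tsv(
            pairs[["chromosome", "distance_bp", "r2"]],
            out / "ld" / f"{pop}.pairs.tsv",
        )
        decay = ld_phase.ld_decay(pairs, max_dist_bp=cfg["ld"]["max_dist_bp"], bin_bp=cfg["ld"]["bin_bp"])
        _write_tsv(decay, out / "ld" / f"{pop}.decay.tsv")
        adj = ld_phase.adjacent_ld(ds)
        thin = ld_phase.thinned_ld(ds, keep_every=cfg["ld"]["thin_keep_every"])
        rows = []
        for name, s in (("adjacent", adj), ("thinned", thin)):
            rows.append(
                {
                    "set": name,
                    "mean_r2": s.mean_r2,
                    "frac_r2_gt_0.2": s.frac_above.get(0.2, np.nan),
                    "frac_r2_gt_0.3": s.frac_above.get(0.3, np.nan),
                    "mean_distance_bp": s.mean_distance_bp,
                    "n_pairs_informative": s.n_pairs_informative,
                    "n_pairs_total": s.n_pairs_total,
                }
            )
        _write_tsv(pd.DataFrame(rows), out / "ld" / f"{pop}.adjacent.tsv")
        info[pop] = {"adjacent_mean_r2": adj.mean_r2, "n_pairs": int(len(pairs))}
    return info


def stage_ne(cfg: dict, out: Path) -> dict:
    info = {}
    for pop in cfg["populations"]:
        pairs_path = out / "ld" / f"{pop}.pairs.tsv"
        if not pairs_path.exists():
            raise StageError(f"missing LD pairs for {pop!r}; run `pigdiv ld` first")
        pairs = pd.read_csv(pairs_path, sep="\t", dtype={"chromosome": str})
        traj = ne.ne_trajectory(pairs, cm_per_mb=cfg["ne"]["cm_per_mb"], r2_offset=cfg["ne"]["r2_offset"])
        _write_tsv(ne.trajectory_to_frame(traj), out / "ne" / f"{pop}.trajectory.tsv")
        recent = [p.ne for p in traj if p.t <= 5 and np.isfinite(p.ne)]
        info[pop] = {"ne_recent_median": float(np.median(recent)) if recent else None}
    return info


def stage_phase(cfg: dict, out: Path) -> dict:
    pops = list(cfg["populations"])
    if len(pops) != 2:
        log.info("phase correlation needs exactly two populations; skipping")
        return {"skipped": "needs two populations"}
    ds1 = load_dataset(_qc_prefix(out, pops[0], "ld"))
    ds2 = load_dataset(_qc_prefix(out, pops[1], "ld"))
    res = ld_phase.phase_correlation(
        ds1, ds2,
        max_dist_bp=cfg["ld"]["max_dist_bp"],
        bin_bp=cfg["ld"]["bin_bp"],
        headline_dist_bp=cfg["phase"]["headline_dist_bp"],
    )
    _write_tsv(res.bins, out / "phase" / "phase_correlation.tsv")
    head = pd.DataFrame(
        [{"headline_dist_bp": res.headline_dist_bp, "phase_corr": res.headline_corr, "n_pairs": res.headline_n}]
    )
    _write_tsv(head, out / "phase" / "headline.tsv")
    return {"headline_corr": res.headline_corr, "n_shared_snps": res.n_shared_snps}


STAGES = (
    ("simulate", stage_simulate),
    ("qc", stage_qc),
    ("inbreeding", stage_inbreeding),
    ("roh", stage_roh),
    ("ld", stage_ld),
    ("ne", stage_ne),
    ("phase", stage_phase),
)


def run_full(user_cfg: dict, out_dir: str | Path) -> dict:
    """Run every stage in order; write a manifest; abort naming a failed stage.

    Partial outputs of a failed run are kept and the manifest carries
    ``status: failed:<stage>``.
    """
    cfg = merge_config(user_cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "software_version": __version__,
        "config": cfg_serializable(cfg),
        "config_hash": config_hash(cfg_serializable(cfg)),
        "stages": {},
        "status": "running",
    }
    try:
        for name, fn in STAGES:
            if name == "simulate" and cfg["simulate"] is None:
                continue
            log.info("stage %s", name)
            manifest["stages"][name] = fn(cfg, out)
    except Exception as exc:
        manifest["status"] = f"failed:{name}"
        _write_manifest(manifest, out)
        raise StageError(f"stage {name!r} failed: {exc}") from exc
    manifest["input_checksums"] = {
        str(p): _sha256(plink_path(spec["plink_prefix"], ".bed"))
        for p, spec in cfg["populations"].items()
        if plink_path(spec["plink_prefix"], ".bed").exists()
    }
    manifest["status"] = "ok"
    _write_manifest(manifest, out)
    return manifest


def cfg_serializable(cfg: dict) -> dict:
    def conv(v):
        if isinstance(v, dict):
            return {k: conv(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [conv(x) for x in v]
        if isinstance(v, synthetic.SplitSpec):
            return {"generation": v.generation, "sizes": list(v.sizes)}
        return v
    return conv(cfg)


def _write_manifest(manifest: dict, out: Path) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
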