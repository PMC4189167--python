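"""End-to-end orchestration: peak tables -> provenance report bundle.

Reads a directory of per-trial peak-table CSVs plus a ``manifest.yaml``
describing the experiment design (sample -> genotype, substrate,
tissue, kind, n_trials), applies the preprocessing rules, and produces
profiles, Sørensen matrices, provenance breakdowns, sharing statistics
and PCA coordinates, optionally written as a report bundle with a
machine-readable index.  Deterministic given the configuration
(including the Monte-Carlo seed).
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import diversity, ordination, peaks as pk, provenance, sharing
from .diversity import RankSumResult
from .peaks import SampleProfile
from .simulate import SimulatedExperiment, read_fixture

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Input or consistency error that should abort the run."""


@dataclass
class RunConfig:
    """Pipeline configuration with the standard preprocessing defaults."""

    input_dir: str | Path = "."
    manifest: str | Path | None = None  # default: input_dir / manifest.yaml
    output_dir: str | Path | None = None
    height_cutoff: float = pk.HEIGHT_CUTOFF
    dimer_max: int = pk.DIMER_MAX
    min_trials_present: int = pk.MIN_TRIALS_PRESENT
    rule3: str = "or"
    pool_tissues: bool = True
    sharing_pool_size: int = sharing.POOL_SIZE
    mc_reps: int = 20_000
    rng_seed: int = 0
    exclusions: list = field(default_factory=list)

    def __post_init__(self):
        if self.height_cutoff <= 0 or self.dimer_max <= 0 or self.min_trials_present <= 0:
            raise ValueError("thresholds must be positive")
        if self.rule3 not in ("or", "and"):
            raise ValueError("rule3 must be 'or' or 'and'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)


@dataclass
class PipelineResult:
    """In-memory report bundle."""

    profiles: dict[str, SampleProfile]
    presence: dict[str, frozenset]
    group_presence: dict[str, frozenset]  # tissue-pooled group -> categories
    breakdowns: dict[tuple[str, str], provenance.ProvenanceBreakdown]
    qs_samples: pd.DataFrame
    qs_groups: pd.DataFrame
    tissue_vs_genotype: RankSumResult | None
    sharing_table: pd.DataFrame
    pca_all: ordination.PCAResult
    pca_plants: ordination.PCAResult | None
    matrix: pd.DataFrame
    filter_log: dict
    manifest: dict


class _WaterControls(dict):
    """Per-trial control intensities.

    A water sample whose trial yielded no surviving peaks is a valid
    zero-intensity control, so unknown trial keys fall back to an empty
    series rather than "missing" whenever any water sample exists.
    """

    def __init__(self, data, have_water: bool):
        super().__init__(data)
        self.have_water = have_water

    def get(self, key, default=None):
        if key in self:
            return self[key]
        if self.have_water:
            idx = pd.MultiIndex.from_arrays([[], []], names=("dye", "size_cat"))
            return pd.Series(dtype=float, index=idx)
        return default


def _water_controls(
    filtered: pd.DataFrame, manifest_samples: Mapping[str, dict]
) -> _WaterControls:
    water_ids = [s for s, m in manifest_samples.items() if m.get("kind") == "water"]
    controls: dict[tuple[int, int], pd.Series] = {}
    for wid in water_ids:
        wdf = filtered[filtered["sample_id"] == wid]
        for key, trial_df in wdf.groupby(["bio_rep", "tech_rep"]):
            controls.setdefault(tuple(key), pk.trial_intensities(trial_df))
    if not water_ids:
        logger.warning("no water-control sample in manifest; intensities uncorrected")
    return _WaterControls(controls, have_water=bool(water_ids))


def build_profiles(
    peaks_df: pd.DataFrame, manifest: dict, config: RunConfig
) -> tuple[dict[str, SampleProfile], dict]:
    """Filter raw peaks and aggregate one profile per non-water sample."""
    samples = manifest.get("samples")
    if not samples:
        raise PipelineError("manifest has no 'samples' section")

    data_ids = set(peaks_df["sample_id"].unique())
    orphans = sorted(data_ids - set(samples))
    if orphans:
        raise PipelineError(
            f"peak tables contain sample(s) absent from the manifest: {orphans}"
        )

    n_raw = len(peaks_df)
    filtered = pk.filter_peaks(peaks_df, config.height_cutoff, config.dimer_max)
    n_after_filter = len(filtered)
    if config.exclusions:
        filtered = pk.remove_excluded_sizes(filtered, config.exclusions)
    n_after_excl = len(filtered)
    filter_log = {
        "raw_peaks": n_raw,
        "discarded_height_or_dimer": n_raw - n_after_filter,
        "discarded_excluded_sizes": n_after_filter - n_after_excl,
        "retained": n_after_excl,
    }
    logger.info("filtering: %s", filter_log)

    controls = _water_controls(filtered, samples)
    profiles: dict[str, SampleProfile] = {}
    for sid, meta in samples.items():
        if meta.get("kind") == "water":
            continue
        sdf = filtered[filtered["sample_id"] == sid]
        if sdf.empty:
            logger.warning("sample %s: no surviving peaks; empty profile", sid)
            idx = pd.MultiIndex.from_arrays([[], []], names=("dye", "size_cat"))
            profiles[sid] = SampleProfile(
                sample_id=sid,
                n_trials=int(meta.get("n_trials", 0) or 0),
                table=pd.DataFrame(
                    {"trial_count": [], "present": [], "mean_adjusted_intensity": []},
                    index=idx,
                ),
            )
            continue
        profiles[sid] = pk.aggregate_profile(
            sdf,
            n_trials=meta.get("n_trials"),
            controls=controls,
            min_trials_present=config.min_trials_present,
        )
    return profiles, filter_log


def _group_of(sid: str, meta: dict) -> str:
    if meta.get("group"):
        return meta["group"]
    if meta.get("kind") == "plant":
        return f"{meta['genotype']}_{meta['substrate']}"
    return sid


def _soils(manifest: dict) -> list[str]:
    design = manifest.get("design", {})
    if "soils" in design:
        return list(design["soils"])
    return sorted(
        sid for sid, m in manifest["samples"].items() if m.get("kind") == "soil"
    )


def tissue_vs_genotype_test(
    presence: Mapping[str, frozenset], manifest: dict
) -> RankSumResult | None:
    """Rank-sum contrast: same-tissue/cross-genotype vs cross-tissue/same-genotype QS.

    Pairs are formed between plant samples on the same substrate.
    Returns None when either group has no pairs.
    """
    plants = [
        (sid, m) for sid, m in manifest["samples"].items()
        if m.get("kind") == "plant" and presence.get(sid)
    ]
    same_tissue, cross_tissue = [], []
    for i, (si, mi) in enumerate(plants):
        for sj, mj in plants[i + 1:]:
            if mi["substrate"] != mj["substrate"]:
                continue
            qs = diversity.sorensen(presence[si], presence[sj])
            if mi["tissue"] == mj["tissue"] and mi["genotype"] != mj["genotype"]:
                same_tissue.append(qs)
            elif mi["tissue"] != mj["tissue"] and mi["genotype"] == mj["genotype"]:
                cross_tissue.append(qs)
    if not same_tissue or not cross_tissue:
        return None
    return diversity.rank_sum_test(same_tissue, cross_tissue)


def analyze(
    profiles: Mapping[str, SampleProfile], manifest: dict, config: RunConfig,
    filter_log: dict | None = None,
) -> PipelineResult:
    """All downstream analyses from aggregated profiles."""
    samples = manifest["samples"]
    presence = {sid: prof.present_set() for sid, prof in profiles.items()}

    group_presence: dict[str, frozenset] = {}
    for sid, meta in samples.items():
        if sid not in presence:
            continue
        group = _group_of(sid, meta)
        group_presence[group] = group_presence.get(group, frozenset()) | presence[sid]

    genotypes = sorted(
        {m["genotype"] for m in samples.values() if m.get("kind") == "plant"}
    )
    soils = _soils(manifest)

    # provenance breakdowns per genotype x growth soil
    breakdowns: dict[tuple[str, str], provenance.ProvenanceBreakdown] = {}
    if len(soils) == 2:
        for g in genotypes:
            seed_ids = [
                sid for sid, m in samples.items()
                if m.get("kind") == "seed" and m.get("genotype") == g
            ]
            seed_set = frozenset().union(*(presence.get(s, frozenset()) for s in seed_ids)) \
                if seed_ids else frozenset()
            sand_set = group_presence.get(f"{g}_sand", frozenset())
            for soil, opposite in ((soils[0], soils[1]), (soils[1], soils[0])):
                plant_set = group_presence.get(f"{g}_{soil}", frozenset())
                if not plant_set:
                    logger.warning("no present peaks for %s on %s; breakdown skipped",
                                   g, soil)
                    continue
                refs = provenance.ReferenceSets.make(
                    seed=seed_set,
                    sand_plant=sand_set,
                    opposite_soil_plant=group_presence.get(f"{g}_{opposite}", frozenset()),
                    same_soil=group_presence.get(soil, frozenset()),
                    opposite_soil=group_presence.get(opposite, frozenset()),
                )
                breakdowns[(g, soil)] = provenance.breakdown(
                    plant_set, refs, rule3=config.rule3
                )
    else:
        logger.warning("found %d soil reference(s); provenance needs exactly 2", len(soils))

    nonempty_samples = {sid: s for sid, s in presence.items() if s}
    qs_samples = (
        diversity.pairwise_qs(nonempty_samples)
        if len(nonempty_samples) >= 2 else pd.DataFrame()
    )
    nonempty_groups = {gid: s for gid, s in group_presence.items() if s}
    qs_groups = (
        diversity.pairwise_qs(nonempty_groups)
        if len(nonempty_groups) >= 2 else pd.DataFrame()
    )

    tvg = tissue_vs_genotype_test(presence, manifest)

    # peak-sharing significance for each genotype's cross-soil plant pair
    sharing_rows = []
    if len(soils) == 2:
        import warnings as _warnings

        for g in genotypes:
            A = group_presence.get(f"{g}_{soils[0]}", frozenset())
            B = group_presence.get(f"{g}_{soils[1]}", frozenset())
            if not A or not B:
                continue
            a, b, c = len(A), len(B), len(A & B)
            N = config.sharing_pool_size
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                p_formula = sharing.sharing_probability(a, b, c, N)
            mc = sharing.mc_sharing(a, b, c, N, reps=config.mc_reps,
                                    rng_seed=config.rng_seed)
            sharing_rows.append({
                "genotype": g, "sample_a": f"{g}_{soils[0]}",
                "sample_b": f"{g}_{soils[1]}", "a": a, "b": b, "c": c, "N": N,
                "p_formula": p_formula,
                "p_hypergeom": sharing.hypergeometric_sharing(a, b, c, N),
                "p_mc": mc.p_ge, "mc_se": mc.se,
            })
    sharing_table = pd.DataFrame(
        sharing_rows,
        columns=["genotype", "sample_a", "sample_b", "a", "b", "c", "N",
                 "p_formula", "p_hypergeom", "p_mc", "mc_se"],
    )

    matrix = pk.profiles_to_matrix(
        [p for p in profiles.values() if not p.table.empty]
    )
    if matrix.shape[1] < 2 or matrix.shape[0] < 2:
        raise PipelineError("too few non-empty profiles for ordination")
    pca_all = ordination.pca_covariance(matrix)
    plant_cols = [
        sid for sid in matrix.columns if samples[sid].get("kind") == "plant"
    ]
    pca_plants = (
        ordination.pca_covariance(matrix[plant_cols]) if len(plant_cols) >= 2 else None
    )

    return PipelineResult(
        profiles=dict(profiles),
        presence=presence,
        group_presence=group_presence,
        breakdowns=breakdowns,
        qs_samples=qs_samples,
        qs_groups=qs_groups,
        tissue_vs_genotype=tvg,
        sharing_table=sharing_table,
        pca_all=pca_all,
        pca_plants=pca_plants,
        matrix=matrix,
        filter_log=filter_log or {},
        manifest=manifest,
    )


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full pipeline from a fixture/real-data directory."""
    input_dir = Path(config.input_dir)
    manifest_path = Path(config.manifest) if config.manifest else input_dir / "manifest.yaml"
    if not manifest_path.exists():
        raise PipelineError(f"manifest not found: {manifest_path}")
    peaks_df, _, manifest = read_fixture(input_dir)
    if peaks_df.empty:
        raise PipelineError(f"no peak tables found under {input_dir}")
    profiles, filter_log = build_profiles(peaks_df, manifest, config)
    result = analyze(profiles, manifest, config, filter_log=filter_log)
    if config.output_dir is not None:
        write_report(result, config)
    return result


def analyze_experiment(
    experiment: SimulatedExperiment, config: RunConfig | None = None
) -> PipelineResult:
    """Run preprocessing + analysis directly on a simulated experiment."""
    config = config or RunConfig()
    profiles, filter_log = build_profiles(experiment.peaks, experiment.manifest, config)
    return analyze(profiles, experiment.manifest, config, filter_log=filter_log)


def write_report(result: PipelineResult, config: RunConfig) -> Path:
    """Write the report bundle; returns the index.json path.

    Every emitted file is declared in the index; floats use a fixed
    format so reruns with the same config are byte-identical.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[str] = []

    def save_tsv(df: pd.DataFrame, name: str, **kw):
        path = out / name
        df.to_csv(path, sep="\t", float_format="%.6g", **kw)
        files.append(name)

    save_tsv(result.matrix, "profiles_matrix.tsv")
    if not result.qs_samples.empty:
        save_tsv(result.qs_samples, "qs_samples.tsv")
    if not result.qs_groups.empty:
        save_tsv(result.qs_groups, "qs_groups.tsv")
    if not result.sharing_table.empty:
        save_tsv(result.sharing_table, "sharing.tsv", index=False)

    if result.breakdowns:
        long_rows = []
        bd_json = {}
        for (g, soil), bd in sorted(result.breakdowns.items()):
            bd_json[f"{g}@{soil}"] = bd.to_dict()
            for cat in provenance.CATEGORIES:
                long_rows.append({
                    "genotype": g, "soil": soil, "category": cat.value,
                    "count": bd.counts.get(cat, 0),
                    "fraction": bd.fraction(cat),
                    "percent": bd.percent(cat),
                })
        save_tsv(pd.DataFrame(long_rows), "breakdowns.tsv", index=False)
        with open(out / "breakdowns.json", "w") as fh:
            json.dump(bd_json, fh, indent=2, sort_keys=True)
        files.append("breakdowns.json")

    save_tsv(result.pca_all.sample_coords, "pca_coords.tsv")
    var = pd.DataFrame({
        "eigenvalue": result.pca_all.eigenvalues,
        "variance_explained": result.pca_all.variance_explained,
    }, index=result.pca_all.sample_coords.columns)
    save_tsv(var, "pca_variance.tsv")
    if result.pca_plants is not None:
        save_tsv(result.pca_plants.sample_coords, "pca_coords_plants.tsv")

    index = {
        "files": sorted(files),
        "config": {k: (str(v) if isinstance(v, Path) else v)
                   for k, v in asdict(config).items()},
        "filter_log": result.filter_log,
        "n_samples": len(result.profiles),
        "tissue_vs_genotype": (
            {"U": result.tissue_vs_genotype.statistic,
             "p": result.tissue_vs_genotype.pvalue,
             "method": result.tissue_vs_genotype.method}
            if result.tissue_vs_genotype else None
        ),
    }
    index_path = out / "index.json"
    with open(index_path, "w") as fh:
        json.dump(index, fh, indent=2, sort_keys=True)
    return index_path
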