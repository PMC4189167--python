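"""Synthetic TRFLP soil-swap experiments with known peak provenance.

The generator emulates a seed/soil swap design: plants of one or more
genotypes grown from non-sterile seed on sterilized sand and on two
geographically distinct soils (generically "soilA"/"soilB"), alongside
profiles of the seeds themselves, the two bulk soils, and water controls.
Every community member is a taxon with fixed forward (6FAM) and reverse
(Max550) terminal fragment sizes, drawn from a global pool of integer
size categories, and belongs to one of three provenance classes:

* seed-inherited taxa occur in seeds, sand-grown plants and plants on
  both soils (vertical transmission);
* promiscuous soil taxa occur in both soils and in plants grown on
  either soil, but not in seeds or sand-grown plants;
* soil-specific taxa occur in exactly one soil and its plants.

Observation noise is a flat per-trial detection probability plus
spurious false peaks at a Poisson rate per trial; water-control trials
contain only false peaks.  A ground-truth map from every generated
non-noise (group, dye, size) peak to its origin supports recovery tests.

Replicate structure follows the TRFLP design the package targets: per
plant tissue 3 biological x 2 technical PCR trials (6 replicates; one
configurable short cell with 2 biological pools, giving 4), and 3 PCR
trials per seed pool.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import peaks as pk

DYES = pk.DYES
TISSUES = ("root", "shoot")

#: default global pool of possible integer fragment-size categories
POOL_SIZE = 314
DEFAULT_SIZE_RANGE = (27, 340)  # 314 distinct integer sizes


class Origin(str, enum.Enum):
    """True origin of a generated peak."""

    SEED_INHERITED = "SEED_INHERITED"
    BOTH_SOILS = "BOTH_SOILS"
    SOIL_SPECIFIC = "SOIL_SPECIFIC"
    NOISE = "NOISE"


@dataclass(frozen=True)
class Taxon:
    taxon_id: str
    fwd_size: int
    rev_size: int
    genus_label: str | None = None


@dataclass(frozen=True)
class TaxonPool:
    """A pool of taxa with distinct terminal fragment sizes per channel."""

    taxa: tuple[Taxon, ...]
    size_range: tuple[int, int]

    def __post_init__(self):
        ids = [t.taxon_id for t in self.taxa]
        if len(set(ids)) != len(ids):
            raise ValueError("taxon_ids must be unique")
        lo, hi = self.size_range
        for t in self.taxa:
            if not (lo <= t.fwd_size <= hi and lo <= t.rev_size <= hi):
                raise ValueError(
                    f"taxon {t.taxon_id}: sizes outside declared range {self.size_range}"
                )

    def __len__(self) -> int:
        return len(self.taxa)


def make_taxon_pool(
    n_taxa: int,
    size_range: tuple[int, int] = DEFAULT_SIZE_RANGE,
    rng_seed: int = 0,
) -> TaxonPool:
    """Draw ``n_taxa`` taxa with distinct integer fragment sizes.

    Forward and reverse sizes are sampled uniformly without replacement
    over the distinct integers in ``size_range`` (so categories never
    collide within a channel).  Reproducible given ``rng_seed``.
    """
    if n_taxa < 1:
        raise ValueError("n_taxa must be >= 1")
    lo, hi = size_range
    if lo < 27 or hi > 1200 or lo > hi:
        raise ValueError(f"size_range must lie within [27, 1200], got {size_range}")
    available = hi - lo + 1
    if n_taxa > available:
        raise ValueError(
            f"n_taxa={n_taxa} exceeds the {available} distinct sizes in range {size_range}"
        )
    rng = np.random.default_rng(rng_seed)
    sizes = np.arange(lo, hi + 1)
    fwd = rng.choice(sizes, size=n_taxa, replace=False)
    rev = rng.choice(sizes, size=n_taxa, replace=False)
    taxa = tuple(
        Taxon(taxon_id=f"t{i:04d}", fwd_size=int(f), rev_size=int(r))
        for i, (f, r) in enumerate(zip(fwd, rev))
    )
    return TaxonPool(taxa=taxa, size_range=(lo, hi))


@dataclass
class AssemblyParams:
    """Community composition and observation-noise parameters.

    Component counts are per genotype for seed-inherited taxa and global
    for soil taxa.  Defaults give ~40 peaks per soil-grown plant with a
    60/25/15 inherited / both-soils / soil-specific split.
    """

    n_seed_taxa: int = 24
    n_promiscuous_taxa: int = 10
    n_soilA_specific: int = 6
    n_soilB_specific: int = 6
    detection_prob: float = 0.9
    false_peak_rate: float = 0.5
    n_bio: int = 3
    n_tech: int = 2
    n_seed_trials: int = 3
    pool_size: int = POOL_SIZE
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("n_seed_taxa", "n_promiscuous_taxa", "n_soilA_specific",
                     "n_soilB_specific"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.detection_prob <= 1.0:
            raise ValueError("detection_prob must be in [0, 1]")
        if self.false_peak_rate < 0:
            raise ValueError("false_peak_rate must be >= 0")
        total = (self.n_seed_taxa + self.n_promiscuous_taxa
                 + self.n_soilA_specific + self.n_soilB_specific)
        if total > self.pool_size:
            raise ValueError(
                f"component counts sum to {total}, exceeding pool_size={self.pool_size}"
            )

    def n_components(self, n_genotypes: int = 1) -> int:
        return (n_genotypes * self.n_seed_taxa + self.n_promiscuous_taxa
                + self.n_soilA_specific + self.n_soilB_specific)


@dataclass
class GroundTruth:
    """Map from (sample_group, dye, size_category) to true origin.

    ``sample_group`` is the tissue-pooled group label, e.g.
    ``"G1_soilA"`` for plants of genotype G1 on soilA, ``"G1_seed"``,
    or ``"soilA"`` for the bulk soil itself.
    """

    labels: dict[tuple[str, str, int], Origin] = field(default_factory=dict)

    def origin(self, group: str, dye: str, size_cat: int) -> Origin:
        return self.labels.get((group, dye, size_cat), Origin.NOISE)

    def categories(self, group: str, origin: Origin | None = None) -> frozenset:
        """Non-noise (dye, size) categories of a group, optionally one origin."""
        return frozenset(
            (dye, size)
            for (g, dye, size), lab in self.labels.items()
            if g == group and (origin is None or lab is origin)
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"sample_group": g, "dye": d, "size_cat": s, "origin": lab.value}
            for (g, d, s), lab in sorted(self.labels.items())
        ]
        return pd.DataFrame(rows, columns=["sample_group", "dye", "size_cat", "origin"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GroundTruth":
        labels = {
            (r.sample_group, r.dye, int(r.size_cat)): Origin(r.origin)
            for r in df.itertuples()
        }
        return cls(labels=labels)


@dataclass
class SimulatedExperiment:
    """Raw peak tables, truth and design manifest of one simulation."""

    peaks: pd.DataFrame  # sample_id, bio_rep, tech_rep, dye, size_bp, height
    truth: GroundTruth
    manifest: dict
    trials: dict[str, list[tuple[int, int]]]  # sample_id -> trial keys


def _true_peak_height(rng: np.random.Generator) -> float:
    # log-normal, median 200 FU, clipped so true peaks always clear the
    # 35-unit cutoff
    return float(max(np.exp(rng.normal(np.log(200.0), 0.5)), 36.0))


def _emit_taxon(rows: list, sample_id: str, bio: int, tech: int,
                taxon: Taxon, rng: np.random.Generator) -> None:
    for dye, size in (("6FAM", taxon.fwd_size), ("Max550", taxon.rev_size)):
        jitter = rng.uniform(-0.4, 0.4)
        rows.append((sample_id, bio, tech, dye, size + jitter, _true_peak_height(rng)))


def _emit_noise(rows: list, sample_id: str, bio: int, tech: int,
                rate: float, size_range: tuple[int, int],
                rng: np.random.Generator) -> None:
    k = rng.poisson(rate)
    lo, hi = size_range
    for _ in range(int(k)):
        dye = DYES[int(rng.integers(len(DYES)))]
        cat = int(rng.integers(lo, hi + 1))
        jitter = rng.uniform(-0.4, 0.4)
        rows.append((sample_id, bio, tech, dye, cat + jitter, float(rng.uniform(35.0, 80.0))))


def _plant_trials(n_bio: int, n_tech: int) -> list[tuple[int, int]]:
    return [(b, t) for b in range(1, n_bio + 1) for t in range(1, n_tech + 1)]


def _record_truth(truth: GroundTruth, group: str,
                  taxa: Iterable[Taxon], origin: Origin) -> None:
    for taxon in taxa:
        truth.labels[(group, "6FAM", taxon.fwd_size)] = origin
        truth.labels[(group, "Max550", taxon.rev_size)] = origin


def simulate_design(
    params: AssemblyParams,
    pool: TaxonPool,
    genotypes: Sequence[str] = ("G1",),
    tissues: Sequence[str] = TISSUES,
    short_cell: tuple[str, str] | None = None,
    short_cell_n_bio: int = 2,
) -> SimulatedExperiment:
    """Simulate a full soil-swap experiment.

    One seed-taxa set is drawn per genotype (disjoint across genotypes);
    the promiscuous and soil-specific taxa are shared by all genotypes.
    ``short_cell`` names an optional (genotype, substrate) combination
    that only has ``short_cell_n_bio`` biological pools (default 2,
    hence 4 PCR trials instead of 6).

    Returns a :class:`SimulatedExperiment`; peak heights of true taxa
    exceed the 35-unit cutoff by construction, false peaks fall in
    35-80 units, and emitted sizes carry +/-0.4 bp sizing jitter around
    their integer category.
    """
    n_genotypes = len(genotypes)
    needed = params.n_components(n_genotypes)
    if needed > len(pool):
        raise ValueError(
            f"design needs {needed} taxa but pool has only {len(pool)}"
        )
    rng = np.random.default_rng(params.rng_seed)

    order = rng.permutation(len(pool))
    cursor = 0

    def take(n: int) -> list[Taxon]:
        nonlocal cursor
        sel = [pool.taxa[i] for i in order[cursor:cursor + n]]
        cursor += n
        return sel

    seed_taxa = {g: take(params.n_seed_taxa) for g in genotypes}
    promiscuous = take(params.n_promiscuous_taxa)
    soil_specific = {"soilA": take(params.n_soilA_specific),
                     "soilB": take(params.n_soilB_specific)}

    # tissue affinity per taxon, fixed across substrates
    tissue_of: dict[str, tuple[str, ...]] = {}
    for taxon in pool.taxa:
        u = rng.random()
        if len(tissues) == 1 or u < 0.35:
            tissue_of[taxon.taxon_id] = (tissues[0],)
        elif u < 0.70:
            tissue_of[taxon.taxon_id] = (tissues[1],)
        else:
            tissue_of[taxon.taxon_id] = tuple(tissues)

    truth = GroundTruth()
    manifest_samples: dict[str, dict] = {}
    trials_of: dict[str, list[tuple[int, int]]] = {}
    rows: list[tuple] = []

    def add_sample(sample_id: str, meta: dict, trial_keys, taxa: Sequence[Taxon]):
        manifest_samples[sample_id] = dict(meta, n_trials=len(trial_keys))
        trials_of[sample_id] = list(trial_keys)
        for bio, tech in trial_keys:
            for taxon in taxa:
                if rng.random() < params.detection_prob:
                    _emit_taxon(rows, sample_id, bio, tech, taxon, rng)
            _emit_noise(rows, sample_id, bio, tech, params.false_peak_rate,
                        pool.size_range, rng)

    soil_community = {
        "soilA": promiscuous + soil_specific["soilA"],
        "soilB": promiscuous + soil_specific["soilB"],
    }

    for g in genotypes:
        # seed pool profile
        sid = f"{g}_seed"
        add_sample(
            sid,
            {"genotype": g, "substrate": "seed", "tissue": None, "kind": "seed",
             "group": sid},
            [(1, t) for t in range(1, params.n_seed_trials + 1)],
            seed_taxa[g],
        )
        _record_truth(truth, sid, seed_taxa[g], Origin.SEED_INHERITED)

        for substrate in ("sand", "soilA", "soilB"):
            if substrate == "sand":
                community = list(seed_taxa[g])
            else:
                community = list(seed_taxa[g]) + soil_community[substrate]
            group = f"{g}_{substrate}"
            n_bio = params.n_bio
            if short_cell is not None and (g, substrate) == tuple(short_cell):
                n_bio = short_cell_n_bio
            for tissue in tissues:
                sid = f"{g}_{substrate}_{tissue}"
                taxa_here = [t for t in community if tissue in tissue_of[t.taxon_id]]
                add_sample(
                    sid,
                    {"genotype": g, "substrate": substrate, "tissue": tissue,
                     "kind": "plant", "group": group},
                    _plant_trials(n_bio, params.n_tech),
                    taxa_here,
                )
            _record_truth(truth, group, seed_taxa[g], Origin.SEED_INHERITED)
            if substrate != "sand":
                _record_truth(truth, group, promiscuous, Origin.BOTH_SOILS)
                _record_truth(truth, group, soil_specific[substrate],
                              Origin.SOIL_SPECIFIC)

    for soil in ("soilA", "soilB"):
        add_sample(
            soil,
            {"genotype": None, "substrate": soil, "tissue": None, "kind": "soil",
             "group": soil},
            _plant_trials(params.n_bio, params.n_tech),
            soil_community[soil],
        )
        _record_truth(truth, soil, promiscuous, Origin.BOTH_SOILS)
        _record_truth(truth, soil, soil_specific[soil], Origin.SOIL_SPECIFIC)

    # water controls: false peaks only
    add_sample(
        "water",
        {"genotype": None, "substrate": None, "tissue": None, "kind": "water",
         "group": "water"},
        _plant_trials(params.n_bio, params.n_tech),
        [],
    )

    peaks_df = pd.DataFrame(
        rows, columns=["sample_id", "bio_rep", "tech_rep", "dye", "size_bp", "height"]
    )
    manifest = {
        "design": {
            "genotypes": list(genotypes),
            "tissues": list(tissues),
            "substrates": ["sand", "soilA", "soilB"],
            "soils": ["soilA", "soilB"],
            "n_bio": params.n_bio,
            "n_tech": params.n_tech,
            "n_seed_trials": params.n_seed_trials,
            "pool_size": params.pool_size,
            "rng_seed": params.rng_seed,
        },
        "samples": manifest_samples,
    }
    return SimulatedExperiment(peaks=peaks_df, truth=truth, manifest=manifest,
                               trials=trials_of)


def simulate_experiment(
    params: AssemblyParams, pool: TaxonPool, genotype: str = "G1"
) -> SimulatedExperiment:
    """Single-genotype convenience wrapper around :func:`simulate_design`."""
    return simulate_design(params, pool, genotypes=(genotype,))


def write_fixture(experiment: SimulatedExperiment, directory) -> list[Path]:
    """Write an experiment as a fixture directory.

    Layout: one CSV per PCR trial named ``{sample_id}_{bio}_{tech}.csv``
    (columns sample_id,bio_rep,tech_rep,dye,size_bp,height; trials with
    no peaks still get a header-valid file), a ``truth.tsv`` sidecar and
    a ``manifest.yaml``.  Floats are written at full repr precision so
    the files round-trip losslessly through :func:`read_fixture`, and
    identical parameters give byte-identical fixtures.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    df = experiment.peaks
    for sample_id, trial_keys in experiment.trials.items():
        sub = df[df["sample_id"] == sample_id]
        for bio, tech in trial_keys:
            trial = sub[(sub["bio_rep"] == bio) & (sub["tech_rep"] == tech)]
            path = directory / f"{sample_id}_{bio}_{tech}.csv"
            trial.to_csv(path, index=False)
            written.append(path)
    truth_path = directory / "truth.tsv"
    experiment.truth.to_frame().to_csv(truth_path, sep="\t", index=False)
    written.append(truth_path)
    manifest_path = directory / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(experiment.manifest, fh, sort_keys=True)
    written.append(manifest_path)
    return written


def read_fixture(directory) -> tuple[pd.DataFrame, GroundTruth | None, dict]:
    """Read a fixture directory back into (peaks, truth, manifest).

    ``truth.tsv`` is optional (real data has no truth sidecar).
    """
    directory = Path(directory)
    manifest_path = directory / "manifest.yaml"
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    frames = [
        pk.read_peak_table(path)
        for path in sorted(directory.glob("*.csv"))
    ]
    peaks_df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=list(pk.REQUIRED_COLUMNS))
    )
    truth = None
    truth_path = directory / "truth.tsv"
    if truth_path.exists():
        tdf = pd.read_csv(truth_path, sep="\t")
        truth = GroundTruth.from_frame(tdf) if not tdf.empty else GroundTruth()
    return peaks_df, truth, manifest
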