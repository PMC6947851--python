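"""Synthetic multi-locus strain collections with controllable group structure.

The generator emulates a rhizobial multi-locus sequence analysis design:
a few host-defined groups (e.g. Vaf/Rlv/Rlt-like), each sampled around a
geographic centroid, sequenced at several housekeeping (hkg) and
symbiotic (sym) loci.  Evolution is an independent-site Jukes–Cantor
process on a known tree: one random root sequence per locus, one
lineage per group running from the root to that group's ancestor at
branch length ``between_group_divergence`` (scaled by per-category and
per-group multipliers), and one tip per strain at
``within_group_divergence`` (scaled by the locus rate and a per-strain
depth factor).  Each strain attaches to its group lineage at a fraction
u ~ Uniform(group_coherence, 1) of the way from the root, so low-
coherence groups are straggly — some members sit nearly as close to
other groups as to their own, which is what makes leave-one-out
assignment genuinely asymmetric.  Substitution counts are Poisson per site, so
the expected p-distance for a total branch length d follows the JC
closed form p = (3/4)(1 − e^(−4d/3)) — which lets the generator be
validated against itself.

Geography places each strain at its group centroid plus Gaussian jitter.
With ``ibd_coupling`` c > 0, (a) group-ancestor branch lengths scale
with the group's mean centroid separation and (b) per-strain depth
factors are rank-matched to the strain's distance from its centroid, so
at c = 1 genetic distances track geographic distances up to noise.

No indels are simulated; gap handling is exercised by hand-written
micro-fixtures in the test suite instead.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .sequence_io import (
    LocusAlignment,
    StrainMetadata,
    write_alignment,
    write_metadata,
)

_BASES = np.array([0, 1, 2, 3], dtype=np.uint8)
_BASE_CHARS = np.frombuffer(b"ACGT", dtype=np.uint8)

FIXTURE_NAMES = ("separated", "null", "ibd", "paperlike")

#: approximate high-mountain study-region centroids (design shape only):
#: (latitude, longitude, jitter SD in km)
DEFAULT_GEOGRAPHY = [
    (43.0, 44.7, 15.0),   # North-Ossetia-like
    (42.5, 47.0, 15.0),   # Dagestan-like
    (40.2, 44.5, 15.0),   # Armenia-like
]


@dataclass
class LocusSpec:
    name: str
    length: int
    category: str  # hkg | sym
    mutation_rate: float = 1.0  # multiplier on both divergence scales

    def __post_init__(self) -> None:
        if self.length < 50:
            raise ValueError(f"{self.name}: locus length must be >= 50")
        if self.mutation_rate < 0:
            raise ValueError(f"{self.name}: negative mutation rate")


@dataclass
class SimConfig:
    n_groups: int
    strains_per_group: list[int]
    loci: list[LocusSpec]
    between_group_divergence: float
    within_group_divergence: float
    geography: list[tuple[float, float, float]] = field(
        default_factory=lambda: list(DEFAULT_GEOGRAPHY)
    )
    ibd_coupling: float = 0.0
    seed: int = 0
    group_names: list[str] | None = None
    #: extra divergence multiplier per category applied to the
    #: group-ancestor branches (e.g. {"sym": 2.0} makes sym ancestors
    #: diverge twice as far as hkg ancestors)
    category_between_multiplier: dict[str, float] = field(default_factory=dict)
    #: per-group multiplier on the ancestor branch (an outgroup-like
    #: group gets a value > 1)
    group_divergence_multiplier: list[float] | None = None
    #: "fixed": every tip at exactly within_group_divergence;
    #: "exponential": per-strain depth factor ~ Exp(1), shared across loci
    tip_length_model: str = "fixed"
    #: per-group ancestry coherence in [0, 1].  Each strain attaches to
    #: its group's lineage at a fraction u ~ Uniform(coherence, 1) of the
    #: way from the root to the group ancestor (drawn once per strain
    #: and gene category).  1 = star-like monophyletic group; lower
    #: values make the group straggly, with some members nearly as close
    #: to the root (hence to other groups) as to their own group.
    group_coherence: list[float] | None = None

    def __post_init__(self) -> None:
        if self.n_groups < 1:
            raise ValueError("need at least one group")
        if len(self.strains_per_group) != self.n_groups:
            raise ValueError("strains_per_group length must equal n_groups")
        if any(k < 2 for k in self.strains_per_group):
            raise ValueError("every group needs at least 2 strains")
        if self.between_group_divergence < 0 or self.within_group_divergence < 0:
            raise ValueError("divergences must be >= 0")
        if not 0 <= self.ibd_coupling <= 1:
            raise ValueError("ibd_coupling must be in [0, 1]")
        if len(self.geography) < self.n_groups:
            raise ValueError("need a geographic centroid per group")
        if any(j < 0 for _, _, j in self.geography):
            raise ValueError("jitter must be >= 0")
        if self.tip_length_model not in ("fixed", "exponential"):
            raise ValueError("tip_length_model must be 'fixed' or 'exponential'")
        if self.group_names is None:
            self.group_names = [f"G{k+1}" for k in range(self.n_groups)]
        if self.group_divergence_multiplier is None:
            self.group_divergence_multiplier = [1.0] * self.n_groups
        if self.group_coherence is None:
            self.group_coherence = [1.0] * self.n_groups
        if len(self.group_coherence) != self.n_groups or any(
            not 0 <= c <= 1 for c in self.group_coherence
        ):
            raise ValueError("group_coherence needs one value in [0,1] per group")


def derive_seed(seed: int, *tokens) -> int:
    """Stable sub-seed below 2^31 from a master seed and string tokens."""
    s = ":".join([str(seed), *map(str, tokens)])
    return zlib.crc32(s.encode()) % (2**31)


def _evolve(seq: np.ndarray, d: float, rng: np.random.Generator) -> np.ndarray:
    """Jukes–Cantor evolution: Poisson(d) substitutions per site, each
    jump uniform over the three other bases."""
    out = seq.copy()
    if d <= 0:
        return out
    k = rng.poisson(d, size=seq.size)
    remaining = k.copy()
    while remaining.max(initial=0) > 0:
        hit = remaining > 0
        jumps = rng.integers(1, 4, size=int(hit.sum())).astype(np.uint8)
        out[hit] = (out[hit] + jumps) % 4
        remaining[hit] -= 1
    return out


def _decode(seq: np.ndarray) -> str:
    return _BASE_CHARS[seq].tobytes().decode("ascii")


def _km_offset_to_degrees(lat: float, dx_km: float, dy_km: float) -> tuple[float, float]:
    dlat = dy_km / 111.32
    dlon = dx_km / (111.32 * math.cos(math.radians(lat)))
    return dlat, dlon


def jc_expected_p(d: float) -> float:
    """Closed-form expected p-distance after total branch length d."""
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


def simulate(
    cfg: SimConfig,
) -> tuple[list[LocusAlignment], list[StrainMetadata], dict]:
    """Generate alignments, metadata, and a truth record; deterministic per seed."""
    rng_geo = np.random.default_rng(derive_seed(cfg.seed, "geo"))
    rng_depth = np.random.default_rng(derive_seed(cfg.seed, "depth"))

    # --- geography ------------------------------------------------------
    from .distances import haversine_km

    meta: list[StrainMetadata] = []
    centroid_dist_km: list[list[float]] = []  # per group, per strain
    strain_ids: list[list[str]] = []
    for g in range(cfg.n_groups):
        lat0, lon0, jit = cfg.geography[g]
        ids_g, dists_g = [], []
        for k in range(cfg.strains_per_group[g]):
            sid = f"{cfg.group_names[g]}-{k+1:02d}"
            dx, dy = rng_geo.normal(0.0, jit, size=2) if jit > 0 else (0.0, 0.0)
            dlat, dlon = _km_offset_to_degrees(lat0, dx, dy)
            lat, lon = lat0 + dlat, lon0 + dlon
            meta.append(
                StrainMetadata(sid, cfg.group_names[g], f"pop{g+1}", lat, lon)
            )
            ids_g.append(sid)
            dists_g.append(haversine_km(lat0, lon0, lat, lon))
        strain_ids.append(ids_g)
        centroid_dist_km.append(dists_g)

    # --- per-strain depth factors (shared across loci) ------------------
    depth: dict[str, float] = {}
    for g in range(cfg.n_groups):
        k = cfg.strains_per_group[g]
        if cfg.tip_length_model == "exponential":
            f = rng_depth.exponential(1.0, size=k)
        else:
            f = np.ones(k)
        c = cfg.ibd_coupling
        if c > 0:
            # rank-match depth factors to distance from the centroid
            geo_rank = np.argsort(np.argsort(centroid_dist_km[g]))
            f_sorted = np.sort(f)
            f_matched = f_sorted[geo_rank]
            f = (1 - c) * f + c * f_matched
        for sid, fv in zip(strain_ids[g], f):
            depth[sid] = float(fv)

    # --- ancestor branch scaling ----------------------------------------
    anc_scale = np.array(cfg.group_divergence_multiplier, dtype=float)
    if cfg.ibd_coupling > 0 and cfg.n_groups > 1:
        cents = [(la, lo) for la, lo, _ in cfg.geography[: cfg.n_groups]]
        mean_sep = np.array(
            [
                np.mean(
                    [
                        haversine_km(*cents[g], *cents[h])
                        for h in range(cfg.n_groups)
                        if h != g
                    ]
                )
                for g in range(cfg.n_groups)
            ]
        )
        rel = mean_sep / mean_sep.mean()
        c = cfg.ibd_coupling
        anc_scale = anc_scale * ((1 - c) + c * rel)

    # --- per-strain lineage attachment points (per gene category) -------
    categories = sorted({l.category for l in cfg.loci})
    attach: dict[tuple[str, str], float] = {}  # (strain, category) -> u
    for cat in categories:
        rng_u = np.random.default_rng(derive_seed(cfg.seed, "attach", cat))
        for g in range(cfg.n_groups):
            lo = cfg.group_coherence[g]
            us = rng_u.uniform(lo, 1.0, size=cfg.strains_per_group[g])
            for sid, u in zip(strain_ids[g], us):
                attach[(sid, cat)] = float(u)

    # --- sequences -------------------------------------------------------
    alignments: list[LocusAlignment] = []
    truth_loci = {}
    for locus in cfg.loci:
        rng = np.random.default_rng(derive_seed(cfg.seed, "locus", locus.name))
        root = rng.integers(0, 4, size=locus.length).astype(np.uint8)
        cat_mult = cfg.category_between_multiplier.get(locus.category, 1.0)
        seqs: dict[str, str] = {}
        anc_branch = {}
        tip_branch = {}
        root_dist = {}  # strain -> divergence of its attachment point from root
        for g in range(cfg.n_groups):
            b = float(
                cfg.between_group_divergence
                * locus.mutation_rate
                * cat_mult
                * anc_scale[g]
            )
            anc_branch[cfg.group_names[g]] = b
            # walk the root -> group-ancestor lineage, branching tips off
            # at each strain's attachment fraction (ascending order)
            order = sorted(strain_ids[g], key=lambda s: attach[(s, locus.category)])
            current = root
            pos = 0.0
            for sid in order:
                u = attach[(sid, locus.category)]
                current = _evolve(current, (u - pos) * b, rng)
                pos = u
                w = float(cfg.within_group_divergence * locus.mutation_rate * depth[sid])
                seqs[sid] = _decode(_evolve(current, w, rng))
                tip_branch[sid] = w
                root_dist[sid] = u * b
        alignments.append(LocusAlignment(locus.name, locus.category, seqs))
        # exact expected p-distance per between-group pair (tree is known)
        exp_between = {}
        for g in range(cfg.n_groups):
            for h in range(g + 1, cfg.n_groups):
                vals = [
                    jc_expected_p(
                        root_dist[si] + root_dist[sj]
                        + tip_branch[si] + tip_branch[sj]
                    )
                    for si in strain_ids[g]
                    for sj in strain_ids[h]
                ]
                exp_between[
                    f"{cfg.group_names[g]}|{cfg.group_names[h]}"
                ] = float(np.mean(vals))
        truth_loci[locus.name] = {
            "category": locus.category,
            "length": locus.length,
            "ancestor_branch": anc_branch,
            "tip_branch": tip_branch,
            "expected_between_p": exp_between,
        }

    truth = {
        "config": {
            "n_groups": cfg.n_groups,
            "strains_per_group": cfg.strains_per_group,
            "between_group_divergence": cfg.between_group_divergence,
            "within_group_divergence": cfg.within_group_divergence,
            "ibd_coupling": cfg.ibd_coupling,
            "tip_length_model": cfg.tip_length_model,
            "seed": cfg.seed,
        },
        "depth_factors": depth,
        "loci": truth_loci,
    }
    return alignments, meta, truth


# ---------------------------------------------------------------------------
# canonical scenarios used throughout the test surface
# ---------------------------------------------------------------------------

def scenario_config(name: str, seed: int = 0) -> SimConfig:
    """The four canonical generator configurations.

    * ``separated`` — three well-separated groups, no within-group
      structure to speak of: every locus should show near-maximal
      differentiation and a fully supported group split.
    * ``null`` — one undifferentiated population arbitrarily split into
      three labelled groups (ancestor divergence zero, fixed tips).
    * ``ibd`` — one metapopulation across three distant sites with full
      isolation-by-distance coupling.
    * ``paperlike`` — the 22-strain, 3-group, 4 hkg + 4 sym design: two
      close groups plus one distant (outgroup-like) third group, with
      sym ancestors diverging twice as far as hkg ancestors.
    """
    if name == "separated":
        return SimConfig(
            n_groups=3,
            strains_per_group=[5, 5, 5],
            loci=[
                LocusSpec("hkgA", 600, "hkg"),
                LocusSpec("hkgB", 600, "hkg"),
                LocusSpec("symA", 600, "sym"),
                LocusSpec("symB", 600, "sym"),
            ],
            between_group_divergence=0.08,
            within_group_divergence=0.003,
            tip_length_model="fixed",
            seed=seed,
        )
    if name == "null":
        return SimConfig(
            n_groups=3,
            strains_per_group=[9, 7, 6],
            loci=[
                LocusSpec("hkgA", 800, "hkg"),
                LocusSpec("hkgB", 800, "hkg"),
            ],
            between_group_divergence=0.0,
            within_group_divergence=0.01,
            tip_length_model="fixed",
            seed=seed,
        )
    if name == "ibd":
        return SimConfig(
            n_groups=3,
            strains_per_group=[8, 7, 7],
            loci=[
                LocusSpec("hkgA", 900, "hkg"),
                LocusSpec("hkgB", 700, "hkg"),
                LocusSpec("hkgC", 600, "hkg"),
                LocusSpec("hkgD", 600, "hkg"),
            ],
            between_group_divergence=0.02,
            within_group_divergence=0.008,
            ibd_coupling=1.0,
            tip_length_model="fixed",
            seed=seed,
        )
    if name == "paperlike":
        return SimConfig(
            n_groups=3,
            group_names=["Vaf", "Rlv", "Rlt"],
            strains_per_group=[9, 7, 6],
            loci=[
                LocusSpec("rrs16S", 900, "hkg", 0.5),
                LocusSpec("dnaK", 700, "hkg", 1.0),
                LocusSpec("gltA", 600, "hkg", 1.0),
                LocusSpec("glnII", 600, "hkg", 1.0),
                LocusSpec("nodA", 550, "sym", 1.0),
                LocusSpec("nodC", 650, "sym", 1.0),
                LocusSpec("nodD", 700, "sym", 1.0),
                LocusSpec("nifH", 600, "sym", 1.0),
            ],
            between_group_divergence=0.008,
            within_group_divergence=0.02,
            category_between_multiplier={"sym": 2.0},
            group_divergence_multiplier=[1.0, 1.0, 3.0],
            # compact focal group, straggly reference group, tight outgroup
            group_coherence=[0.5, 0.0, 0.9],
            tip_length_model="exponential",
            seed=seed,
        )
    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")


def make_fixture(name: str, seed: int, outdir: str | Path) -> Path:
    """Write a canonical scenario to disk: FASTA per locus, metadata CSV,
    truth YAML.  Returns the output directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = scenario_config(name, seed)
    alignments, meta, truth = simulate(cfg)
    for aln in alignments:
        write_alignment(aln, outdir / f"{aln.locus_name}.fasta")
    write_metadata(meta, outdir / "metadata.csv")
    with open(outdir / "truth.yaml", "w") as fh:
        yaml.safe_dump(truth, fh, sort_keys=True)
    return outdir
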