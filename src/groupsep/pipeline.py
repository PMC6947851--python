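"""Run the full analysis from one YAML config with a single seed.

Stages: read alignments + metadata → per-category concatenates →
distance matrices → N_st (bootstrap), jackknife/CAD, Mantel panel,
bootstrapped NJ trees, hkg/sym diversity-ratio comparison.  Each
analysis gets a sub-seed derived by stable hashing of
(seed, analysis, locus), so rerunning a subset reproduces the full
run's numbers.  A failure in one locus is logged into the manifest and
does not abort the others; only an all-loci failure is fatal.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .differentiation import (
    compare_category_diversity,
    nst_bootstrap,
    nucleotide_diversity,
)
from .distances import distance_matrix, geographic_matrix, write_matrix_tsv
from .jackknife import jk_assign, jk_report
from .mantel import mantel_panel
from .phylogeny import bootstrap_support, write_newick
from .sequence_io import (
    LocusAlignment,
    concatenate,
    groups_from_metadata,
    read_locus_alignment,
    read_metadata,
)
from .synthetic_data import derive_seed

logger = logging.getLogger("groupsep")


@dataclass
class RunConfig:
    loci: list[dict]                 # {name, path, category}
    metadata: str
    seed: int
    output_dir: str
    analyses: list[str] = field(
        default_factory=lambda: ["nst", "jk", "mantel", "trees", "diversity_ratio"]
    )
    group_pairs: list[list[str]] | None = None
    n_boot: int = 1000
    n_perm: int = 9999
    distance_model: str = "p_distance"
    tree_model: str = "k2p"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "seed" not in raw:
            raise ValueError("config must set a seed")
        cfg = cls(**raw)
        missing = [l["path"] for l in cfg.loci if not Path(l["path"]).exists()]
        if not Path(cfg.metadata).exists():
            missing.append(cfg.metadata)
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")
        return cfg


def _setup_logging(outdir: Path) -> None:
    logger.setLevel(logging.INFO)
    if not any(isinstance(h, logging.StreamHandler) for h in logger.handlers):
        logger.addHandler(logging.StreamHandler(sys.stderr))
    fh = logging.FileHandler(outdir / "run.log")
    logger.addHandler(fh)


def run(config: RunConfig) -> Path:
    """Execute all requested analyses; returns the output directory."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    errors: list[str] = []

    meta = read_metadata(config.metadata)
    groups = groups_from_metadata(meta)
    alignments = [
        read_locus_alignment(l["path"], l["name"], l["category"])
        for l in config.loci
    ]
    units: list = list(alignments)
    for cat in ("hkg", "sym"):
        members = [a for a in alignments if a.category == cat]
        if members:
            units.append(concatenate(members, cat))

    pairs = config.group_pairs
    if pairs is None:
        labels = [g for g, mem in groups.items() if len(mem) >= 2]
        pairs = [[labels[i], labels[j]] for i in range(len(labels)) for j in range(i + 1, len(labels))]

    summary: list[str] = []

    if "nst" in config.analyses:
        rows = []
        for unit in units:
            name = unit.locus_name
            present = set(unit.sequences)
            for ga, gb in pairs:
                mem = {
                    ga: [s for s in groups[ga] if s in present],
                    gb: [s for s in groups[gb] if s in present],
                }
                try:
                    res = nst_bootstrap(
                        unit, mem, n_boot=config.n_boot,
                        seed=derive_seed(config.seed, "nst", name, ga, gb),
                    )
                    rows.append(
                        {
                            "locus": name, "group_a": ga, "group_b": gb,
                            "R_s": res.R_s, "R_t": res.R_t, "N_st": res.N_st,
                            "ci95_low": res.ci95[0], "ci95_high": res.ci95[1],
                            "n_boot": res.n_boot,
                            "n_undefined_reps": res.n_undefined_reps,
                        }
                    )
                except Exception as e:  # noqa: BLE001 - collected
                    errors.append(f"nst/{name}/{ga}-{gb}: {e}")
        if rows:
            df = pd.DataFrame(rows)
            df.to_csv(outdir / "nst.tsv", sep="\t", index=False)
            summary.append(f"N_st: {len(rows)} comparisons -> nst.tsv")

    if "jk" in config.analyses:
        jk_results = []
        for unit in units:
            try:
                present = set(unit.sequences)
                mem = {
                    g: [s for s in m if s in present]
                    for g, m in groups.items()
                }
                mem = {g: m for g, m in mem.items() if len(m) >= 2}
                dm = distance_matrix(unit, config.distance_model)
                jk_results.append(
                    jk_assign(
                        dm, mem,
                        seed=derive_seed(config.seed, "jk", unit.locus_name),
                        locus_or_concat=unit.locus_name,
                    )
                )
            except Exception as e:  # noqa: BLE001 - collected
                errors.append(f"jk/{unit.locus_name}: {e}")
        if jk_results:
            jk_report(jk_results).to_csv(outdir / "jk.tsv", sep="\t", index=False)
            pd.concat(
                [r.audit.assign(locus=r.locus_or_concat) for r in jk_results]
            ).to_csv(outdir / "jk_audit.tsv", sep="\t", index=False)
            summary.append(f"jackknife: {len(jk_results)} units -> jk.tsv, jk_audit.tsv")

    if "mantel" in config.analyses:
        with_coords = [m for m in meta if m.latitude is not None]
        try:
            results = mantel_panel(
                units, with_coords, model=config.distance_model,
                n_perm=config.n_perm, seed=derive_seed(config.seed, "mantel"),
            )
            pd.DataFrame(
                {
                    "locus": [r.locus_or_concat for r in results],
                    "r": [r.r for r in results],
                    "p_value": [r.p_value for r in results],
                    "n_perm": [r.n_perm for r in results],
                    "n_strains": [r.n_strains for r in results],
                    "significant_0.05": [
                        (r.p_value < 0.05) if not np.isnan(r.p_value) else False
                        for r in results
                    ],
                }
            ).to_csv(outdir / "mantel.tsv", sep="\t", index=False)
            for r in results:
                if r.error:
                    errors.append(f"mantel/{r.error}")
            summary.append(f"Mantel: {len(results)} units -> mantel.tsv")
        except Exception as e:  # noqa: BLE001 - collected
            errors.append(f"mantel: {e}")

    if "trees" in config.analyses:
        treedir = outdir / "trees"
        treedir.mkdir(exist_ok=True)
        n_ok = 0
        for unit in units:
            try:
                tree = bootstrap_support(
                    unit, model=config.tree_model, n_boot=config.n_boot,
                    seed=derive_seed(config.seed, "tree", unit.locus_name),
                )
                write_newick(tree, treedir / f"{unit.locus_name}.nwk")
                n_ok += 1
            except Exception as e:  # noqa: BLE001 - collected
                errors.append(f"tree/{unit.locus_name}: {e}")
        summary.append(f"trees: {n_ok} Newick files -> trees/")

    if "diversity_ratio" in config.analyses:
        rows = []
        for g, mem in groups.items():
            if len(mem) < 2:
                continue
            try:
                hkg_div = [
                    nucleotide_diversity(a, [s for s in mem if s in a.sequences], scope=g)
                    for a in alignments if a.category == "hkg"
                ]
                sym_div = [
                    nucleotide_diversity(a, [s for s in mem if s in a.sequences], scope=g)
                    for a in alignments if a.category == "sym"
                ]
                if hkg_div and sym_div:
                    ratio, ci = compare_category_diversity(
                        hkg_div, sym_div, n_boot=config.n_boot,
                        seed=derive_seed(config.seed, "ratio", g),
                    )
                    rows.append(
                        {"group": g, "sym_hkg_ratio": ratio,
                         "ci95_low": ci[0], "ci95_high": ci[1]}
                    )
            except Exception as e:  # noqa: BLE001 - collected
                errors.append(f"diversity_ratio/{g}: {e}")
        if rows:
            pd.DataFrame(rows).to_csv(outdir / "diversity_ratio.tsv", sep="\t", index=False)
            summary.append(f"diversity ratio: {len(rows)} groups -> diversity_ratio.tsv")

    manifest = {
        "groupsep_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config": {
            "loci": config.loci, "metadata": config.metadata,
            "analyses": config.analyses, "n_boot": config.n_boot,
            "n_perm": config.n_perm, "distance_model": config.distance_model,
            "tree_model": config.tree_model,
        },
        "errors": errors,
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    (outdir / "summary.txt").write_text("\n".join(summary) + "\n")
    produced = [p for p in outdir.rglob("*") if p.is_file()]
    if len(produced) <= 2 and errors:  # only manifest+summary -> nothing worked
        raise RuntimeError(f"all analyses failed: {errors}")
    return outdir
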