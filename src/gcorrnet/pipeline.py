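"""End-to-end pipeline: simulate -> filter -> ldsc -> corr -> cluster ->
stability -> effdf, driven by one JSON config with a global seed.

Every stage writes its artifacts under the output directory in the
documented TSV/JSON formats and appends to a run manifest (input hashes,
per-stage seeds and record counts, library versions). All randomness flows
from the global seed through named per-stage substreams, so rerunning the
same config reproduces byte-identical outputs, and a stage rerun in
isolation with its derived seed matches the full run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .corrmat import align_signs, assemble
from .effdf import EffectiveTests, effective_df, read_zmatrix
from .graphs import LouvainClusterer, build_cluster_graph, display_graph, hclust_order
from .ldsc import fit_bivariate, fit_univariate
from .stability import stability_run
from .sumstats import (
    SNPFilterConfig,
    filter_sumstats,
    harmonize_pair,
    read_include_list,
    read_ldscores,
    read_sumstats,
)
from .synth import SimulationConfig, write_dataset

logger = logging.getLogger(__name__)

STAGES = ["simulate", "filter", "ldsc", "corr", "cluster", "stability", "effdf"]


class ConfigError(ValueError):
    """Invalid run configuration (caught before any stage executes)."""


class StageError(RuntimeError):
    """A stage failed; partial outputs of earlier stages are preserved."""


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed, below 2^31."""
    ss = np.random.SeedSequence([int(global_seed), STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass
class RunConfig:
    """Structured configuration for :func:`run_all` (one JSON document)."""

    out_dir: str
    seed: int = 1
    simulate: dict | None = None
    paths: dict = field(default_factory=dict)
    filter: dict = field(default_factory=dict)
    ldsc: dict = field(default_factory=dict)
    cluster: dict = field(default_factory=dict)
    stability: dict = field(default_factory=dict)
    effdf: dict = field(default_factory=dict)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def validate(self) -> None:
        if not isinstance(self.seed, int):
            raise ConfigError("seed must be an integer")
        for key in ("seed",):
            for section in (self.cluster, self.stability):
                if key in section and not isinstance(section[key], int):
                    raise ConfigError(f"{key} must be an integer")
        if self.simulate is None:
            for key in ("sumstats", "ldscores"):
                if key not in self.paths:
                    raise ConfigError(f"paths.{key} is required without a "
                                      "simulate section")
            missing = [
                str(p)
                for p in [*self.paths["sumstats"], self.paths["ldscores"],
                          *( [self.paths["include_list"]]
                             if self.paths.get("include_list") else [] )]
                if not Path(p).exists()
            ]
            if missing:
                raise ConfigError(f"missing input path(s): {', '.join(missing)}")
        zmat = self.effdf.get("zmat")
        if zmat and not Path(zmat).exists():
            raise ConfigError(f"missing input path(s): {zmat}")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute every stage in order; returns (and writes) the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "libs": {"numpy": np.__version__, "pandas": pd.__version__},
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in STAGES},
        "stages": [],
    }

    def record(stage: str, counts: dict, paths: dict) -> None:
        manifest["stages"].append(
            {
                "stage": stage,
                "counts": counts,
                "outputs": {k: {"path": str(p), "sha256": _sha256(p)}
                            for k, p in paths.items() if Path(p).is_file()},
            }
        )

    def guard(stage: str):
        class _Guard:
            def __enter__(self):
                logger.info("stage %s", stage)

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise StageError(f"stage {stage!r} failed: {exc}") from exc

        return _Guard()

    # 1. simulate (or ingest existing files)
    with guard("simulate"):
        if config.simulate is not None:
            sim_cfg = SimulationConfig(
                **{**config.simulate, "seed": stage_seed(config.seed, "simulate")}
            )
            ds = write_dataset(sim_cfg, out / "simulate")
            trait_names = list(sim_cfg.trait_names)
            sumstat_paths = {t: ds["paths"][t] for t in trait_names}
            ldscore_path = ds["paths"]["ldscores"]
            include_path = ds["paths"]["include_list"]
            record("simulate", ds["counts"], ds["paths"])
        else:
            sumstat_paths = {Path(p).stem.replace(".sumstats", ""): p
                             for p in config.paths["sumstats"]}
            trait_names = list(sumstat_paths)
            ldscore_path = config.paths["ldscores"]
            include_path = config.paths.get("include_list")
            record("simulate", {t: None for t in trait_names},
                   {"ldscores": ldscore_path, **sumstat_paths})

    # 2. filter
    with guard("filter"):
        ldscores = read_ldscores(ldscore_path)
        include = read_include_list(include_path) if include_path else None
        fcfg = SNPFilterConfig(
            maf_min=config.filter.get("maf_min", 0.01),
            hwe_p_min=config.filter.get("hwe_p_min", 1e-8),
            include_list=include,
            exclude_regions=config.filter.get(
                "exclude_regions", ["6:26000000-34000000"]
            ),
        )
        fdir = out / "filter"
        fdir.mkdir(exist_ok=True)
        filtered: dict[str, pd.DataFrame] = {}
        reports = {}
        fpaths = {}
        for t in trait_names:
            stats = read_sumstats(sumstat_paths[t])
            kept, rep = filter_sumstats(stats, fcfg)
            filtered[t] = kept
            reports[t] = rep.__dict__
            p = fdir / f"{t}.sumstats.tsv"
            kept.to_csv(p, sep="\t", index=False)
            fpaths[t] = p
        with open(fdir / "filter_report.json", "w") as fh:
            json.dump(reports, fh, indent=2)
        fpaths["report"] = fdir / "filter_report.json"
        record("filter", {t: len(v) for t, v in filtered.items()}, fpaths)

    # 3. ldsc
    with guard("ldsc"):
        n_blocks = config.ldsc.get("n_blocks", 200)
        m_override = config.ldsc.get("m_override")
        uni = {
            t: fit_univariate(filtered[t], ldscores, m_override=m_override,
                              n_blocks=n_blocks)
            for t in trait_names
        }
        biv = {}
        log_rows = []
        for a_idx in range(len(trait_names)):
            for b_idx in range(a_idx + 1, len(trait_names)):
                ta, tb = trait_names[a_idx], trait_names[b_idx]
                s1, s2 = harmonize_pair(filtered[ta], filtered[tb])
                f = fit_bivariate(s1, s2, ldscores, uni[ta], uni[tb],
                                  n_blocks=n_blocks, m_override=m_override)
                biv[(b_idx, a_idx)] = f
                log_rows.append(
                    {"trait1": ta, "trait2": tb, "rg": f.rg, "rg_se": f.rg_se,
                     "p_rg": f.p_rg, "gcov": f.gcov,
                     "cross_intercept": f.cross_intercept, "n_snps": f.n_snps}
                )
        ldir = out / "ldsc"
        ldir.mkdir(exist_ok=True)
        with open(ldir / "univariate.json", "w") as fh:
            json.dump({t: f.to_dict() for t, f in uni.items()}, fh, indent=2)
        pd.DataFrame(log_rows).to_csv(ldir / "pairs.tsv", sep="\t", index=False,
                                      float_format="%.17g")
        record("ldsc", {"univariate": len(uni), "bivariate": len(biv)},
               {"univariate": ldir / "univariate.json",
                "pairs": ldir / "pairs.tsv"})

    # 4. corr
    with guard("corr"):
        m = assemble(trait_names, biv)
        m = align_signs(m)
        cpaths = m.write(out / "corr")
        record("corr", {"traits": m.n_traits,
                        "vech_dim": m.V.shape[0],
                        "flipped": int(m.flipped.sum())}, cpaths)

    # 5. cluster
    with guard("cluster"):
        cl_seed = config.cluster.get("seed", stage_seed(config.seed, "cluster"))
        clus = LouvainClusterer(seed=cl_seed).fit(m)
        order = hclust_order(m, method=config.cluster.get("linkage", "average"))
        edges = build_cluster_graph(m)
        disp, cent = display_graph(m)
        gdir = out / "cluster"
        gdir.mkdir(exist_ok=True)
        clus.partition_.write(gdir / "partition.tsv")
        edges.write(gdir / "edges.tsv")
        disp.write(gdir / "display_edges.tsv")
        cent.to_csv(gdir / "centrality.tsv", sep="\t", float_format="%.17g")
        with open(gdir / "ordering.txt", "w") as fh:
            fh.write("\n".join(order) + "\n")
        record("cluster",
               {"clusters": len(set(clus.membership_.values())),
                "q": clus.modularity_, "edges": len(edges.edges)},
               {"partition": gdir / "partition.tsv",
                "edges": gdir / "edges.tsv",
                "display_edges": gdir / "display_edges.tsv",
                "centrality": gdir / "centrality.tsv",
                "ordering": gdir / "ordering.txt"})

    # 6. stability
    with guard("stability"):
        st_seed = config.stability.get("seed", stage_seed(config.seed, "stability"))
        n_res = config.stability.get("n", 1000)
        focal = config.stability.get("focal")
        cm = stability_run(m, n=n_res, seed=st_seed, focal=focal)
        sdir = out / "stability"
        sdir.mkdir(exist_ok=True)
        cm.write(sdir / "concordance.tsv")
        spaths = {"concordance": sdir / "concordance.tsv"}
        if focal:
            with open(sdir / "focal.json", "w") as fh:
                json.dump({"focal": focal,
                           "co_cluster": cm.co_cluster_with(focal).to_dict()},
                          fh, indent=2)
            spaths["focal"] = sdir / "focal.json"
        record("stability", {"n_resamples": cm.n_resamples}, spaths)

    # 7. effdf
    with guard("effdf"):
        alpha = config.effdf.get("alpha", 0.05)
        zmat_path = config.effdf.get("zmat")
        if zmat_path:
            res = EffectiveTests(alpha=alpha).fit(read_zmatrix(zmat_path)).result_
            source = str(zmat_path)
        else:
            # effective number of independent traits in the aligned matrix
            S_fill = np.where(np.isfinite(m.S), m.S, 0.0)
            np.fill_diagonal(S_fill, 1.0)
            res = effective_df((S_fill + S_fill.T) / 2, alpha=alpha)
            source = "genetic correlation matrix"
        edir = out / "effdf"
        edir.mkdir(exist_ok=True)
        with open(edir / "effdf.json", "w") as fh:
            json.dump({"source": source, **res.to_dict()}, fh, indent=2)
        record("effdf", {"m": res.m, "meff": res.meff,
                         "alpha_corrected": res.alpha_corrected},
               {"effdf": edir / "effdf.json"})

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
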