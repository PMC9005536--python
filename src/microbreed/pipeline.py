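"""End-to-end orchestration of the host-genomic microbiome workflow.

Stages: simulate (or ingest) -> log-ratio transform -> GRM -> per-trait
univariate GBLUP (full and reduced, DIC + Bayes factor) -> bivariate fits
against CH4 (r_gCH4, P0, correlated response) -> breeding-panel selection ->
pairwise covariance assembly + bending -> prediction scenarios 1-3 ->
truncation responses -> dGEBV co-abundance network. Every stage writes TSV
outputs under the run directory and the run manifest records seed, settings
and data hashes so a rerun reproduces all outputs bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import compositional as comp
from . import gblup, network, selection
from .genomics import build_grm
from .simulate import SimConfig, simulate_genotypes, simulate_microbiome_counts, simulate_traits

logger = logging.getLogger("microbreed")

__all__ = ["RunConfig", "run_full"]


@dataclass
class RunConfig:
    """Declarative configuration of a full run; thresholds default to the
    study's operating values (core RA 0.001 %, panel RA 0.01 %, DIC <= -20,
    corrected BF > 3, P0 >= 0.95, bending tolerance 0.001, selected fractions
    1-50 %)."""

    outdir: str = "microbreed_run"
    seed: int = 0
    # simulation block (used when no input paths are given)
    n_animals: int = 120
    n_snps: int = 500
    n_microbial_traits: int = 4
    h2_ch4: float = 0.33
    h2_microbial: float = 0.33
    rg_ch4: float = -0.8
    n_extra_features: int = 10
    # optional input paths (TSV dialects)
    genotypes_path: str | None = None
    traits_path: str | None = None
    abundance_path: str | None = None
    # thresholds
    core_min_ra: float = 1e-5
    panel_min_ra: float = 1e-4
    dic_delta_max: float = -20.0
    bf_corrected_min: float = 3.0
    p0_min: float = 0.95
    bend_tolerance: float = 0.001
    fractions: tuple = (0.01, 0.05, 0.10, 0.20, 0.30, 0.40, 0.50)
    panel_cap: int = 30
    # MCMC
    n_iter: int = 4000
    burn_in: int = 1000
    thin: int = 5
    # network
    corr_threshold: float = 0.70
    min_degree: int = 2
    knn_keep_fraction: float = 0.80
    mcl_inflation: float = 2.0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**d)
        if isinstance(cfg.fractions, list):
            cfg.fractions = tuple(cfg.fractions)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _derived_seed(master: int, *tokens) -> int:
    text = ":".join(str(t) for t in (master, *tokens))
    return zlib.crc32(text.encode()) & 0x7FFFFFFF


def _spec(cfg: RunConfig, *tokens) -> gblup.ModelSpec:
    return gblup.ModelSpec(n_iter=cfg.n_iter, burn_in=cfg.burn_in, thin=cfg.thin,
                           seed=_derived_seed(cfg.seed, *tokens))


def _file_hash(path: Path) -> str:
    return hashlib.sha1(path.read_bytes()).hexdigest()


def run_full(config: RunConfig | dict) -> dict:
    """Execute every stage; returns the run report (also written as JSON).

    Any stage failure raises with the stage name and an inventory of the
    outputs already written.
    """
    cfg = config if isinstance(config, RunConfig) else RunConfig.from_dict(config)
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": asdict(cfg), "stages": {}, "outputs": []}
    stage = "setup"

    def _done(name: str, t0: float) -> None:
        report["stages"][name] = round(time.perf_counter() - t0, 3)
        logger.info("stage %s finished in %.2fs", name, report["stages"][name])

    try:
        # ------------------------------------------------------------------
        stage = "simulate"
        t0 = time.perf_counter()
        t = cfg.n_microbial_traits + 1
        rg = np.eye(t)
        rg[0, 1:] = rg[1:, 0] = cfg.rg_ch4 * np.linspace(1.0, 0.75, t - 1)
        g0, r0 = _nearest_valid_covariances(
            np.array([cfg.h2_ch4] + [cfg.h2_microbial] * (t - 1)), rg,
            np.array([3.9 / cfg.h2_ch4] + [1.0] * (t - 1)),
        )
        sim = SimConfig(n_animals=cfg.n_animals, n_snps=cfg.n_snps, n_traits=t,
                        G0_true=g0, R0_true=r0, seed=cfg.seed)
        rng = np.random.default_rng(cfg.seed)
        genotypes = simulate_genotypes(sim, rng)
        grm = build_grm(genotypes)
        traits, truth = simulate_traits(genotypes, sim, rng, grm=grm)
        # microbial phenotypes are latent ALR values -> counts -> back-transform
        latent = traits.phenotypes.iloc[:, 1:].to_numpy()
        latent = np.column_stack([latent] + [
            rng.standard_normal(cfg.n_animals) * 0.5
            for _ in range(cfg.n_extra_features)
        ])
        counts = simulate_microbiome_counts(
            latent, sim, rng, mode="gene", sample_ids=traits.animal_ids,
            feature_ids=(list(traits.phenotypes.columns[1:])
                         + [f"bg_{i}" for i in range(cfg.n_extra_features)]
                         + ["reference_gene"]),
        )
        counts.to_tsv(out / "abundance_genes.tsv")
        traits.phenotypes[["CH4"]].join(traits.design).to_csv(
            out / "traits.tsv", sep="\t")
        report["outputs"] += ["abundance_genes.tsv", "traits.tsv"]
        _done(stage, t0)

        # ------------------------------------------------------------------
        stage = "transform"
        t0 = time.perf_counter()
        core = comp.filter_core(counts, min_mean_ra=cfg.core_min_ra)
        positive = comp.gbm_zero_replace(core)
        alr = comp.alr_transform(positive, "reference_gene")
        alr.to_tsv(out / "alr_genes.tsv")
        report["outputs"].append("alr_genes.tsv")
        _done(stage, t0)

        # ------------------------------------------------------------------
        stage = "grm"
        t0 = time.perf_counter()
        grm.to_tsv(out / "grm.tsv")
        report["outputs"].append("grm.tsv")
        _done(stage, t0)

        # ------------------------------------------------------------------
        stage = "univariate"
        t0 = time.perf_counter()
        y_ch4 = traits.phenotypes["CH4"]
        factor = traits.fixed_factor
        trait_table = pd.concat([y_ch4, alr.data], axis=1)
        n_tests = trait_table.shape[1] - 1
        uni_rows = []
        uni_fits = {}
        for name in trait_table.columns:
            spec = _spec(cfg, "uni", name)
            fit = gblup.fit_univariate(trait_table[name], spec, grm, fixed_factor=factor)
            red = gblup.fit_univariate(trait_table[name],
                                       _spec(cfg, "uni-red", name), grm,
                                       fixed_factor=factor, include_genomic=False)
            h2 = gblup.heritability_from_samples(fit)
            _, _, delta = gblup.dic(fit, red)
            _, bf_c = gblup.bayes_factor(fit, red, n_tests=max(n_tests, 1))
            uni_fits[name] = fit
            uni_rows.append({
                "trait": name, "h2_median": h2.median, "h2_hpd_low": h2.hpd_low,
                "h2_hpd_high": h2.hpd_high, "classification": h2.extra["classification"],
                "dic_delta": delta, "bf_corrected": bf_c,
                "h2_significant": (delta <= cfg.dic_delta_max) and (bf_c > cfg.bf_corrected_min),
            })
        uni_df = pd.DataFrame(uni_rows).set_index("trait")
        _done(stage, t0)

        # ------------------------------------------------------------------
        stage = "bivariate"
        t0 = time.perf_counter()
        sg_ch4 = uni_fits["CH4"].samples["sg2"]
        bi_rows = []
        bi_fits = {}
        for name in alr.data.columns:
            y2 = pd.concat([y_ch4, alr.data[name]], axis=1)
            fit = gblup.fit_bivariate(y2, _spec(cfg, "bi", name), grm,
                                      fixed_factor=factor)
            rg_s = gblup.rg_samples(fit)
            rg_sum = gblup.summarize(rg_s)
            h2j = gblup.h2_samples(fit, trait=1)
            resp = selection.correlated_response(
                selection.selection_intensity(0.30), np.sqrt(h2j), rg_s,
                np.sqrt(fit.samples["G0"][:, 0, 0]),
            )
            bi_fits[("CH4", name)] = fit
            bi_rows.append({
                "trait": name, "rg_median": rg_sum.median, "rg_hpd_low": rg_sum.hpd_low,
                "rg_hpd_high": rg_sum.hpd_high, "p0": rg_sum.p0,
                "response_median": resp["median"], "response_p0": resp["p0"],
            })
        bi_df = pd.DataFrame(bi_rows).set_index("trait")
        master = uni_df.join(bi_df, how="left")
        ra = comp.relative_abundance(core).data.mean(axis=0)
        master["mean_ra"] = ra.reindex(master.index)
        master["occupancy_all"] = (core.data > 0).all(axis=0).reindex(master.index)
        master.to_csv(out / "significance_table.tsv", sep="\t")
        report["outputs"].append("significance_table.tsv")
        _done(stage, t0)

        # ------------------------------------------------------------------
        stage = "panel"
        t0 = time.perf_counter()
        candidates = master.drop(index="CH4").dropna(subset=["rg_median"])
        panel = selection.select_breeding_panel(
            candidates, min_ra=cfg.panel_min_ra, p0_min=cfg.p0_min, cap=cfg.panel_cap)
        panel.to_csv(out / "breeding_panel.tsv", sep="\t")
        report["outputs"].append("breeding_panel.tsv")
        report["panel_size"] = int(len(panel))
        _done(stage, t0)

        # ------------------------------------------------------------------
        stage = "covariance"
        t0 = time.perf_counter()
        panel_traits = ["CH4"] + list(panel.index)
        pair_fits = {k: v for k, v in bi_fits.items() if k[1] in panel.index}
        for i, a in enumerate(panel.index):
            for b in list(panel.index)[i + 1:]:
                y2 = alr.data[[a, b]]
                pair_fits[(a, b)] = gblup.fit_bivariate(
                    y2, _spec(cfg, "pair", a, b), grm, fixed_factor=factor)
        if len(panel_traits) >= 2:
            cov = selection.assemble_covariance(pair_fits, panel_traits, "CH4")
            cov.G0, glog = selection.bend_matrix(cov.G0, cfg.bend_tolerance)
            cov.R0, rlog = selection.bend_matrix(cov.R0, cfg.bend_tolerance)
            cov.bending_log = {"G0": glog["bent"], "R0": rlog["bent"]}
            pd.DataFrame(cov.G0, index=panel_traits, columns=panel_traits).to_csv(
                out / "G0_bent.tsv", sep="\t")
            pd.DataFrame(cov.R0, index=panel_traits, columns=panel_traits).to_csv(
                out / "R0_bent.tsv", sep="\t")
            report["outputs"] += ["G0_bent.tsv", "R0_bent.tsv"]
        else:
            cov = None
        _done(stage, t0)

        # ------------------------------------------------------------------
        stage = "scenarios"
        t0 = time.perf_counter()
        if cov is not None and len(panel_traits) >= 2:
            pheno = pd.concat([y_ch4, alr.data[list(panel.index)]], axis=1)
            scen_rows = []
            for scen in (1, 2, 3):
                res = selection.predict_scenarios(
                    pheno, factor, grm, cov, scen, _spec(cfg, "scen", scen))
                usable = [p for p in cfg.fractions
                          if int(np.floor(p * len(res.gebv_mean))) >= 1]
                responses = selection.response_to_selection(res, usable)
                tab = selection.response_summary_table(responses)
                tab.insert(0, "scenario", scen)
                scen_rows.append(tab)
                pd.DataFrame({
                    "gebv_mean": res.gebv_mean, "gebv_sd": res.gebv_sd,
                    "accuracy": res.accuracies,
                }).to_csv(out / f"scenario_{scen}_gebv.tsv", sep="\t")
                report["outputs"].append(f"scenario_{scen}_gebv.tsv")
                report[f"scenario_{scen}_mean_accuracy"] = res.mean_accuracy
            pd.concat(scen_rows).to_csv(out / "responses.tsv", sep="\t", index=False)
            report["outputs"].append("responses.tsv")
        _done(stage, t0)

        # ------------------------------------------------------------------
        stage = "network"
        t0 = time.perf_counter()
        dgebvs = {}
        for name, fit in uni_fits.items():
            if name == "CH4":
                continue
            dg, _ = gblup.deregress_gebv(fit, grm)
            dgebvs[name] = dg
        dgebv_df = pd.DataFrame(dgebvs)
        if dgebv_df.shape[1] >= 3:
            graph = network.build_graph(dgebv_df, cfg.corr_threshold, cfg.min_degree)
            if graph.number_of_edges():
                graph = network.prune_knn_edges(graph, cfg.knn_keep_fraction)
                graph, labels = network.mcl_cluster(graph, cfg.mcl_inflation)
            network.write_graph(graph, edgelist_path=out / "network_edges.tsv",
                                clusters_path=out / "network_clusters.tsv")
            report["outputs"] += ["network_edges.tsv", "network_clusters.tsv"]
            report["n_network_nodes"] = graph.number_of_nodes()
        _done(stage, t0)

        # ------------------------------------------------------------------
        stage = "manifest"
        t0 = time.perf_counter()
        manifest = {
            "seed": cfg.seed,
            "config": asdict(cfg),
            "output_hashes": {name: _file_hash(out / name) for name in report["outputs"]},
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        report["manifest"] = str(out / "manifest.json")
        _done(stage, t0)
    except Exception as err:
        raise RuntimeError(
            f"pipeline failed at stage {stage!r}; outputs so far: {report['outputs']}"
        ) from err
    return report


def _nearest_valid_covariances(h2, rg, pvar):
    """Covariances from (h2, rg, phenotypic var) with the correlation matrix
    projected to PSD if the requested pattern is not jointly attainable."""
    from .simulate import covariances_from_h2_rg

    vals = np.linalg.eigvalsh(rg)
    if vals.min() < 0:
        d, u = np.linalg.eigh(rg)
        rg = (u * np.clip(d, 1e-6, None)) @ u.T
        s = np.sqrt(np.diag(rg))
        rg = rg / np.outer(s, s)
    return covariances_from_h2_rg(np.asarray(h2, float), rg, np.asarray(pvar, float))
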