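"""End-to-end orchestration: simulate/ingest → thin → decorrelate → niche
models → overlap & randomization tests → PNO/ancestral tolerances → ARC →
DTT/MDI → pPCA/MANOVA, from a single config with derived per-stage seeds.

Defaults mirror a standard phyloclimatic study setup: |r| ≤ 0.9 variable
filter, 10×(59/41) AUC replication with a 0.7 gate, a 5-occurrence modeling
minimum, 100-replicate randomization tests at 95 % confidence, 50 PNO bins,
and 1000 simulations for DTT/MDI and the MANOVA null.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from phyloniche import geodata, synthetic, enm, overlap, evolution, disparity, multivariate
from phyloniche.phylo import Tree
from phyloniche.synthetic import stage_rng

log = logging.getLogger("phyloniche")


@dataclass
class RunConfig:
    """Settings for one full pipeline run."""

    # inputs: either a directory of .asc files + occurrences + newick, or simulate
    env_dir: str | None = None
    occurrences: str | None = None
    tree_file: str | None = None
    simulate: bool = False
    sim: dict = field(default_factory=dict)     # overrides for synthetic.SimConfig
    clades: dict[str, str] = field(default_factory=dict)
    group_labels: dict[str, str] = field(default_factory=dict)   # e.g. barrier side
    # pre-processing
    thin_distance: float = 1.0
    r_threshold: float = 0.9
    priority: list[str] | None = None
    # niche models
    beta: float = 1.0
    max_iter: int = 1000
    auc_gate: float = 0.7
    auc_replicates: int = 10
    train_frac: float = 0.59
    min_occurrences: int = 5
    # randomization tests
    test_replicates: int = 100
    conf: float = 0.95
    background_buffer: float = 5.0
    run_tests: bool = True
    # niche evolution
    pno_bins: int = 50
    atp_samples: int = 100
    arc_weighting: str = "ft"
    arc_permutations: int = 1000
    dtt_sims: int = 1000
    manova_sims: int = 1000
    n_components: int = 4
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _load_inputs(cfg: RunConfig, out: Path):
    if cfg.simulate:
        sim = synthetic.SimConfig(seed=cfg.seed, **cfg.sim)
        stack = synthetic.simulate_env_stack(sim)
        tree = synthetic.simulate_tree(sim.n_tips, sim.birth_rate, seed=sim.seed)
        root = synthetic.NicheSpec(
            mu={v: float(np.mean(stack.values(v))) for v in stack.variables},
            sigma={v: float(np.std(stack.values(v))) / 2 for v in stack.variables},
        )
        rates = {
            v: (sim.bm_rate_rel * float(np.std(stack.values(v)))) ** 2
            for v in stack.variables
        }
        specs = synthetic.evolve_niches(
            tree, root, bm_rate=rates,
            regime=sim.regime, ou_alpha=sim.ou_alpha, seed=sim.seed,
        )
        occs = {
            name: synthetic.sample_occurrences(
                stack, spec, sim.n_occurrences, seed=sim.seed, species=name
            )
            for name, spec in specs.items()
        }
        geodata.write_env_stack(stack, out / "env")
        geodata.write_occurrences(occs.values(), out / "occurrences.csv")
        (out / "tree.nwk").write_text(tree.to_newick() + "\n")
        truth = pd.DataFrame(
            [
                {"species": n, **{f"mu_{v}": s.mu[v] for v in s.mu},
                 **{f"sigma_{v}": s.sigma[v] for v in s.sigma}}
                for n, s in specs.items()
            ]
        )
        truth.to_csv(out / "truth.csv", index=False)
        return stack, occs, tree
    if not (cfg.env_dir and cfg.occurrences and cfg.tree_file):
        raise ValueError("need env_dir, occurrences and tree_file unless simulate=true")
    paths = sorted(Path(cfg.env_dir).glob("*.asc"))
    stack = geodata.read_env_stack(paths)
    occs = geodata.read_occurrences(cfg.occurrences)
    tree = Tree.from_newick(Path(cfg.tree_file).read_text())
    return stack, occs, tree


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Run every stage and write artifacts under ``out_dir``.

    Returns the manifest (also written as ``manifest.json``): per-stage
    settings, seeds, timings, species exclusions, and headline numbers.
    Deterministic: the same config and seed reproduce identical outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(cfg), "stages": {}}

    def stage(name):
        t0 = time.time()

        def done(**info):
            manifest["stages"][name] = {"seconds": round(time.time() - t0, 3), **info}
            log.info("stage %-12s %6.2fs %s", name, time.time() - t0, info)

        return done

    # ingest / simulate ----------------------------------------------------
    end = stage("ingest")
    stack, occs, tree = _load_inputs(cfg, out)
    end(n_variables=len(stack.variables), n_species=len(occs), n_tips=tree.n_tips)

    # thinning -------------------------------------------------------------
    end = stage("thin")
    occs = {
        name: geodata.thin_occurrences(o.validate(stack), cfg.thin_distance)
        for name, o in occs.items()
    }
    end(points={n: len(o) for n, o in occs.items()})

    # variable decorrelation ----------------------------------------------
    end = stage("filter_vars")
    stack, var_report = geodata.filter_variables(
        stack, cfg.r_threshold, cfg.priority or list(stack.variables)
    )
    var_report.to_csv(out / "variable_filter.csv", index=False)
    end(retained=stack.variables, dropped=var_report["variable"].tolist())

    # niche models ---------------------------------------------------------
    end = stage("enm")
    models: dict[str, enm.NicheModel] = {}
    excluded: list[str] = []
    auc_rows = []
    for name, occ in occs.items():
        try:
            models[name] = enm.fit_maxent(
                stack, occ, beta=cfg.beta, max_iter=cfg.max_iter,
                min_occurrences=cfg.min_occurrences,
            )
        except enm.TooFewOccurrencesError as exc:
            log.warning("%s", exc)
            excluded.append(name)
            continue
        rep = enm.evaluate_auc(
            stack, occ, n_replicates=cfg.auc_replicates, train_frac=cfg.train_frac,
            gate=cfg.auc_gate, beta=cfg.beta, max_iter=cfg.max_iter,
            rng=stage_rng(cfg.seed, f"auc:{name}"),
        )
        auc_rows.append({"species": name, "mean_auc": rep.mean_auc, "passed": rep.passed})
        geodata.write_surface(models[name].logistic_grid(stack), stack,
                              out / f"enm_{name}.asc")
    auc_df = pd.DataFrame(auc_rows)
    auc_df.to_csv(out / "auc.csv", index=False)
    end(modeled=list(models), excluded=excluded,
        mean_auc=dict(zip(auc_df["species"], auc_df["mean_auc"])) if len(auc_df) else {})

    # prune tree and labels to modeled species ----------------------------
    modeled = [n for n in tree.tip_names if n in models]
    clades = {s: c for s, c in cfg.clades.items() if s in models}

    # overlap matrices -----------------------------------------------------
    end = stage("overlap")
    ov = overlap.overlap_matrix(models)
    ov.D.to_csv(out / "overlap_D.tsv", sep="\t")
    ov.I.to_csv(out / "overlap_I.tsv", sep="\t")
    end(n_species=len(ov.species))

    # identity & background tests -----------------------------------------
    if clades and cfg.run_tests:
        end = stage("tests")
        id_verdicts: dict[frozenset, str] = {}
        bg_verdicts: dict[frozenset, str] = {}
        test_rows = []
        for clade, pairs in overlap.within_clade_pairs(clades).items():
            for a, b in pairs:
                key = frozenset((a, b))
                res_i = overlap.identity_test(
                    stack, occs[a], occs[b], n_replicates=cfg.test_replicates,
                    conf=cfg.conf, beta=cfg.beta, max_iter=cfg.max_iter,
                    rng=stage_rng(cfg.seed, f"identity:{a}:{b}"),
                )
                id_verdicts[key] = res_i.verdict
                verdicts = []
                for x, y in ((a, b), (b, a)):
                    res_b = overlap.background_test(
                        stack, occs[x], occs[y], n_replicates=cfg.test_replicates,
                        conf=cfg.conf, beta=cfg.beta, max_iter=cfg.max_iter,
                        buffer_cells=cfg.background_buffer,
                        rng=stage_rng(cfg.seed, f"background:{x}:{y}"),
                    )
                    verdicts.append(res_b.verdict)
                    test_rows.append(
                        {"clade": clade, "pair": f"{a}|{b}", "test": "background",
                         "direction": res_b.direction, "observed_D": res_b.observed["D"],
                         "lower": res_b.lower, "upper": res_b.upper,
                         "verdict": res_b.verdict}
                    )
                # a pair shows conservatism/divergence if either direction does
                if "conservatism" in verdicts:
                    bg_verdicts[key] = "conservatism"
                elif "divergence" in verdicts:
                    bg_verdicts[key] = "divergence"
                else:
                    bg_verdicts[key] = "n.s."
                test_rows.append(
                    {"clade": clade, "pair": f"{a}|{b}", "test": "identity",
                     "direction": "pooled", "observed_D": res_i.observed["D"],
                     "lower": res_i.lower, "upper": res_i.upper, "verdict": res_i.verdict}
                )
        pd.DataFrame(test_rows).to_csv(out / "randomization_tests.tsv", sep="\t", index=False)
        summary = overlap.summarize_within_clade(clades, bg_verdicts)
        summary.to_csv(out / "background_summary.tsv", sep="\t", index=False)
        end(pairs=sum(len(p) for p in overlap.within_clade_pairs(clades).values()))

    # PNO profiles and weighted means -------------------------------------
    end = stage("pno")
    profiles: dict[str, dict[str, evolution.PNOProfile]] = {v: {} for v in stack.variables}
    wm_rows = []
    pno_rows = []
    for v in stack.variables:
        edges = evolution.variable_bins(stack, v, cfg.pno_bins)
        for name, model in models.items():
            prof = evolution.compute_pno(model, stack, v, edges=edges)
            profiles[v][name] = prof
            wm_rows.append({"species": name, "variable": v,
                            "weighted_mean": evolution.pno_weighted_mean(prof)})
            for mid, m in zip(prof.midpoints, prof.mass):
                pno_rows.append({"species": name, "variable": v, "value": mid, "mass": m})
    pd.DataFrame(pno_rows).to_csv(out / "pno.tsv", sep="\t", index=False)
    wm = pd.DataFrame(wm_rows).pivot(index="species", columns="variable",
                                     values="weighted_mean")
    wm.to_csv(out / "pno_weighted_means.tsv", sep="\t")
    end(variables=list(stack.variables))

    # the phylogenetic stages need every tip modeled: prune excluded species
    if set(modeled) != set(tree.tip_names):
        dropped = sorted(set(tree.tip_names) - set(modeled))
        log.warning("pruning unmodeled species from the tree: %s", dropped)
        tree = tree.prune(modeled)
        (out / "tree_pruned.nwk").write_text(tree.to_newick() + "\n")

    # ancestral tolerances -------------------------------------------------
    end = stage("ancestral")
    atp_rows = []
    for v in stack.variables:
        atp = evolution.ancestral_tolerance(
            tree, profiles[v], n_samples=cfg.atp_samples,
            rng=stage_rng(cfg.seed, f"atp:{v}"),
        )
        for _, row in atp.summary.iterrows():
            atp_rows.append({"variable": v, **row.to_dict()})
    pd.DataFrame(atp_rows).to_csv(out / "ancestral_tolerances.tsv", sep="\t", index=False)
    end(n_samples=cfg.atp_samples)

    # age-range correlation ------------------------------------------------
    end = stage("arc")
    arc = evolution.age_range_correlation(
        tree, ov, weighting=cfg.arc_weighting, n_permutations=cfg.arc_permutations,
        conf=cfg.conf, rng=stage_rng(cfg.seed, "arc"),
    )
    arc.table.to_csv(out / "arc_nodes.tsv", sep="\t", index=False)
    (out / "arc.json").write_text(json.dumps(
        {"slope": arc.slope, "intercept": arc.intercept, "p_value": arc.p_value,
         "weighting": arc.weighting}, indent=2))
    end(slope=arc.slope, p_value=arc.p_value)

    # disparity through time -----------------------------------------------
    end = stage("dtt")
    mdi_summary = {}
    for v in stack.variables:
        x = wm[v].loc[tree.tip_names].to_numpy()
        res = disparity.mdi(tree, x, n_sims=cfg.dtt_sims, conf=cfg.conf,
                            rng=stage_rng(cfg.seed, f"dtt:{v}"))
        res.table.to_csv(out / f"dtt_{v}.tsv", sep="\t", index=False)
        mdi_summary[v] = {"mdi": res.mdi, "rate": res.rate}
    (out / "mdi.json").write_text(json.dumps(mdi_summary, indent=2))
    end(**{v: round(d["mdi"], 4) for v, d in mdi_summary.items()})

    # pPCA / MANOVA --------------------------------------------------------
    end = stage("multivariate")
    ppca = multivariate.phylo_pca(tree, wm)
    ppca.scores.to_csv(out / "ppca_scores.tsv", sep="\t")
    pd.DataFrame(ppca.eigenvectors, index=ppca.variables,
                 columns=ppca.scores.columns).to_csv(out / "ppca_loadings.tsv", sep="\t")
    manova_info = None
    groups = {s: g for s, g in cfg.group_labels.items() if s in models}
    counts = pd.Series(list(groups.values())).value_counts() if groups else pd.Series([])
    if len(counts) > 1 and counts.min() >= 2:
        k = min(cfg.n_components, tree.n_tips - len(set(groups.values())) - 1)
        scores = ppca.scores.iloc[:, :k]
        man = multivariate.phylo_manova(
            tree, scores, groups, n_sims=cfg.manova_sims,
            rng=stage_rng(cfg.seed, "manova"),
        )
        manova_info = {"F": man.F, "df": man.df, "p_value": man.p_value,
                       "wilks_lambda": man.wilks_lambda, "n_components": k}
        (out / "manova.json").write_text(json.dumps(manova_info, indent=2))
    elif groups:
        log.warning("MANOVA skipped: every group needs >= 2 modeled species")
    end(explained=[round(f, 4) for f in ppca.explained.tolist()],
        manova=manova_info)

    manifest["seed"] = cfg.seed
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
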