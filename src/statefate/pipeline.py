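"""End-to-end orchestration of the synthetic cell-state study.

One YAML config drives every stage — synthesize data, assign states,
infer/impute activities, build and simulate the Boolean model, run the
knockout screen, train/evaluate/attribute the classifier — with one
explicit seed per stochastic stage.  Each stage writes its outputs under
the run directory and the run ends with a JSON manifest of seeds, stage
durations and output checksums; rerunning the same config reproduces
identical output checksums.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import io as sfio
from .activity import ActivityProfile, impute_phospho_activity
from .assign import GeneModuleSet, classify_dominant_state, estimate_compositions, label_clusters
from .boolnet import similarity_score, simulate_to_steady_state, synthesize_rules
from .koscreen import SimConfig, run_knockout_screen
from .predictor import (
    attribute_predictions,
    compare_paired_samples,
    predict_states,
    scaled_hyperparams,
    train_classifier,
    training_set_from_screen,
)
from .synthetic import (
    generate_activity_profiles,
    generate_network_with_attractors,
    generate_paired_omics,
    generate_reference_and_bulk,
)

__all__ = ["DEFAULT_CONFIG", "load_config", "run_pipeline"]

log = logging.getLogger("statefate")

DEFAULT_CONFIG: dict = {
    "stages": {
        "synthetic": True,
        "assign": True,
        "activity": True,
        "boolnet": True,
        "koscreen": True,
        "predict": True,
    },
    "synthetic": {
        "seed": 11,
        "n_nodes": 20,
        "n_inputs": 2,
        "mean_in_degree": 2.5,
        "genes_per_state": 30,
        "n_cells_per_state": 50,
        "n_samples": 100,
        "dirichlet_alpha": [1.0, 1.0, 1.0, 1.0],
        "nb_dispersion": 10.0,
        "cohort_seed": 1,
        "n_profiles_per_state": 50,
        "flip_prob": 0.05,
        "gauss_sd": 0.3,
        "profiles_seed": 5,
        "paired_entities": 200,
        "paired_noise_sd": 0.1,
        "paired_seed": 3,
    },
    "koscreen": {"n_traj": 100, "max_time": 50.0, "seed": 23, "z_mode": "per_start"},
    "predict": {"model_kind": "boosted_trees", "seed": 7},
}


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    for key, value in user.items():
        if isinstance(value, Mapping) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Stage:
    def __init__(self, manifest: dict, name: str, outdir: Path):
        self.manifest, self.name, self.outdir = manifest, name, outdir
        self.outputs: list[Path] = []

    def __enter__(self):
        log.info("stage %s: start", self.name)
        self._t0 = time.perf_counter()
        return self

    def path(self, filename: str) -> Path:
        p = self.outdir / filename
        self.outputs.append(p)
        return p

    def __exit__(self, exc_type, exc, tb):
        if exc_type is not None:
            log.error("stage %s: FAILED (%s); partial outputs kept in %s",
                      self.name, exc, self.outdir)
            raise RuntimeError(f"pipeline stage {self.name!r} failed: {exc}") from exc
        self.manifest["stages"][self.name] = {
            "duration_s": round(time.perf_counter() - self._t0, 3),
            "outputs": {str(p.relative_to(self.outdir)): _sha256(p) for p in self.outputs},
        }
        log.info("stage %s: done", self.name)


def run_pipeline(config: dict, outdir) -> dict:
    """Execute enabled stages in dependency order; return the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", {})
    manifest: dict = {"config": config, "stages": {}, "metrics": {}}

    state: dict = {}

    if stages.get("synthetic", True):
        with _Stage(manifest, "synthetic", outdir) as st:
            scfg = config["synthetic"]
            truth = generate_network_with_attractors(
                n_nodes=scfg["n_nodes"],
                n_inputs=scfg["n_inputs"],
                mean_in_degree=scfg["mean_in_degree"],
                seed=scfg["seed"],
            )
            ref, ref_labels, bulk, props = generate_reference_and_bulk(
                truth,
                genes_per_state=scfg["genes_per_state"],
                n_cells_per_state=scfg["n_cells_per_state"],
                n_samples=scfg["n_samples"],
                dirichlet_alpha=tuple(scfg["dirichlet_alpha"]),
                nb_dispersion=scfg["nb_dispersion"],
                seed=scfg["cohort_seed"],
            )
            profiles, profile_labels = generate_activity_profiles(
                truth,
                n_per_state=scfg["n_profiles_per_state"],
                flip_prob=scfg["flip_prob"],
                gauss_sd=scfg["gauss_sd"],
                seed=scfg["profiles_seed"],
            )
            paired = generate_paired_omics(
                n_entities=scfg["paired_entities"],
                noise_sd=scfg["paired_noise_sd"],
                seed=scfg["paired_seed"],
            )
            sfio.write_sif(truth.network, st.path("network.sif"))
            sfio.write_node_signs(truth.network, st.path("node_signs.tsv"))
            truth.logic.to_json(st.path("logic.json"))
            sfio.write_count_matrix(ref, st.path("reference_counts.tsv"))
            ref_labels.to_csv(st.path("reference_labels.tsv"), sep="\t")
            sfio.write_count_matrix(bulk, st.path("bulk_counts.tsv"))
            props.to_csv(st.path("true_proportions.tsv"), sep="\t", index_label="sample")
            sfio.write_activity_tsv(profiles, st.path("activity_profiles.tsv"))
            profile_labels.to_csv(st.path("activity_labels.tsv"), sep="\t")
            truth.write_manifest(st.path("truth.json"))
            modules = GeneModuleSet(
                modules={
                    f"module_{s}": {g for g in ref.index if g.startswith(f"G_{s}_")}
                    for s in truth.cell_states
                },
                universe=set(ref.index),
            )
            modules.to_gmt(st.path("modules.gmt"))
            state.update(
                truth=truth, ref=ref, ref_labels=ref_labels, bulk=bulk, props=props,
                profiles=profiles, profile_labels=profile_labels, paired=paired,
                modules=modules,
            )

    if stages.get("assign", True):
        with _Stage(manifest, "assign", outdir) as st:
            truth = state["truth"]
            # pseudo-clusters: each state's cells contribute their marker block
            rng = np.random.default_rng(101)
            markers_by_cluster = {}
            for s in truth.cell_states:
                block = sorted(g for g in state["ref"].index if g.startswith(f"G_{s}_"))
                picked = list(rng.choice(block, size=max(5, len(block) * 2 // 3), replace=False))
                markers_by_cluster[f"cluster_{s}"] = picked
            enrich = label_clusters(markers_by_cluster, state["modules"])
            enrich.scores.to_csv(st.path("cluster_enrichment.tsv"), sep="\t", index_label="cluster")
            comp = estimate_compositions(state["bulk"], state["ref"], state["ref_labels"])
            dominant = classify_dominant_state(comp)
            comp.proportions.to_csv(st.path("compositions.tsv"), sep="\t", index_label="sample")
            with open(st.path("dominant_states.json"), "w") as fh:
                json.dump(dominant, fh, indent=1, sort_keys=True)
            truth_labels = truth.labels
            acc = float(np.mean([dominant[s] == truth_labels[s] for s in truth_labels]))
            rmse = float(
                np.sqrt(((comp.proportions - state["props"]) ** 2).to_numpy().mean())
            )
            manifest["metrics"]["assign"] = {
                "dominant_state_accuracy": acc,
                "proportion_rmse": rmse,
            }
            state.update(comp=comp, dominant=dominant)

    if stages.get("activity", True):
        with _Stage(manifest, "activity", outdir) as st:
            ref_phos, ref_rna, test_rna, true_phos = state["paired"]
            imp, fallback = impute_phospho_activity(
                ActivityProfile(ref_phos.to_dict(), "ref", "phospho"),
                ActivityProfile(ref_rna.to_dict(), "ref", "rna"),
                ActivityProfile(test_rna.to_dict(), "test", "rna"),
            )
            imp_s = imp.to_series().reindex(true_phos.index)
            r = float(np.corrcoef(imp_s, true_phos)[0, 1])
            imp_s.rename("imputed_phospho").to_csv(st.path("imputed_phospho.tsv"), sep="\t")
            bool_profiles = (state["profiles"] > 0).astype(int)
            bool_profiles.to_csv(st.path("boolean_profiles.tsv"), sep="\t", index_label="sample")
            manifest["metrics"]["activity"] = {
                "imputation_pearson_r": r,
                "imputation_fallbacks": len(fallback),
            }
            state["bool_profiles"] = bool_profiles

    if stages.get("boolnet", True):
        with _Stage(manifest, "boolnet", outdir) as st:
            truth = state["truth"]
            targets = truth.network.target_states()
            logic, report = synthesize_rules(truth.network, targets)
            logic.to_json(st.path("synthesized_logic.json"))
            with open(st.path("boolnet_rules.txt"), "w") as fh:
                fh.write(logic.to_boolnet_text())
            steady = {}
            for name, tgt in targets.items():
                clamp = {n: tgt[n] for n in logic.inputs}
                res = simulate_to_steady_state(
                    logic, tgt, clamped=clamp, n_traj=50, max_time=50.0,
                    seed=config["koscreen"]["seed"],
                )
                steady[name] = res.state
            sim = pd.DataFrame(
                {
                    b: {a: similarity_score(steady[a], steady[b]) for a in steady}
                    for b in steady
                }
            )
            sim.to_csv(st.path("state_similarity.tsv"), sep="\t", index_label="state")
            manifest["metrics"]["boolnet"] = {
                "nodes": len(truth.network.nodes),
                "edges": len(truth.network.edges),
                "unsatisfiable_nodes": len(report.unsatisfiable),
            }
            state.update(logic=logic, steady=steady)

    if stages.get("koscreen", True):
        with _Stage(manifest, "koscreen", outdir) as st:
            kcfg = config["koscreen"]
            screen = run_knockout_screen(
                state["logic"],
                state["steady"],
                SimConfig(
                    n_traj=kcfg["n_traj"],
                    max_time=kcfg["max_time"],
                    seed=kcfg["seed"],
                    z_mode=kcfg["z_mode"],
                ),
            )
            screen.long_table().to_csv(st.path("ko_screen.tsv"), sep="\t", index=False)
            manifest["metrics"]["koscreen"] = {
                "n_simulations": screen.n_simulations,
                "n_converged": int(sum(screen.converged.values())),
            }
            state["screen"] = screen

    if stages.get("predict", True):
        with _Stage(manifest, "predict", outdir) as st:
            pcfg = config["predict"]
            train = training_set_from_screen(state["screen"], state["steady"])
            hp = scaled_hyperparams(pcfg["model_kind"], len(train.features))
            clf = train_classifier(train, pcfg["model_kind"], hp, seed=pcfg["seed"])
            report = predict_states(clf, state["bool_profiles"], truth=state["profile_labels"])
            with open(st.path("predictions.json"), "w") as fh:
                json.dump(report.predictions, fh, indent=1, sort_keys=True)
            if report.confusion is not None:
                report.confusion.to_csv(st.path("confusion.tsv"), sep="\t", index_label="truth")
            manifest["metrics"]["predict"] = {
                "per_class_balanced_accuracy": report.per_class_balanced_accuracy,
            }
            if pcfg["model_kind"] == "boosted_trees":
                labels = state["profile_labels"]
                states = list(state["truth"].cell_states)
                primary_ids = labels.index[labels == states[1]][:5]
                recurrent_ids = labels.index[labels == states[0]][:5]
                prim = state["bool_profiles"].loc[primary_ids]
                recur = state["bool_profiles"].loc[recurrent_ids]
                recur.index = prim.index  # paired patients: same ids, later tumor
                attr_p = attribute_predictions(clf, prim)
                attr_r = attribute_predictions(clf, recur)
                pred_p = predict_states(clf, prim).predictions
                pred_r = predict_states(clf, recur).predictions
                transitions = compare_paired_samples(attr_p, attr_r, pred_p, pred_r)
                with open(st.path("paired_transitions.json"), "w") as fh:
                    json.dump(
                        {
                            sid: {
                                "state_before": t.state_before,
                                "state_after": t.state_after,
                                "top_supporting": t.ranked_supporting[:5],
                                "n_changed": len(t.changed_features),
                            }
                            for sid, t in transitions.items()
                        },
                        fh,
                        indent=1,
                        sort_keys=True,
                    )
                manifest["metrics"]["predict"]["attribution_additivity_error"] = max(
                    attr_p.additivity_error(), attr_r.additivity_error()
                )

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    return manifest
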