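"""Configuration-driven orchestration of the full cohort analysis.

A :class:`PipelineConfig` collects every stage threshold (noise floor,
minimum mapped reads, prevalence, replicate cap, forest runs, q and fold
thresholds, StARS and bootstrap settings) plus the group design — one
case group against one or more control groups — and a single master
seed from which each stage deterministically derives its own.
``run_pipeline`` executes the stages in the fixed order

    replicate cap -> prevalence filter -> CLR -> diversity/dissimilarity
    -> signature selection -> consensus differential abundance ->
    per-group association networks -> network comparison -> functional
    capacity

writing every stage output plus a provenance manifest to a bundle
directory.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import composition, da, functional, io, network, signatures, synthetic

__all__ = ["PipelineConfig", "run_pipeline", "default_synthetic_config"]


@dataclass
class PipelineConfig:
    """All stage parameters and the cohort design in one place."""

    # --- input: either TSV paths or a synthetic recipe -------------------
    abundance_tsv: str | None = None
    metadata_tsv: str | None = None
    synthetic: dict | None = None  # kwargs for the synthetic cohort recipe

    # --- group design -----------------------------------------------------
    case_group: str = "IBD"
    control_groups: list[str] = field(default_factory=lambda: ["nonIBD", "Healthy"])
    #: raw-group -> classifier-label merge (e.g. pool external healthy cohorts)
    label_merge: dict[str, str] = field(default_factory=dict)

    # --- stage thresholds -------------------------------------------------
    noise_floor: float = 1e-5
    min_mapped_reads: int = 250_000
    prevalence_threshold: float = 0.90
    replicate_cap: int = 5
    rfc_runs: int = 100
    rfc_trees: int = 500
    alpha: float = 0.05
    fold_threshold: float = 2.0
    n_lambdas: int = 30
    stars_subsamples: int = 20
    stars_beta: float = 0.1
    bootstrap_r: int = 50
    bootstrap_f: float = 0.8
    train_fraction: float = 0.70
    #: node set for network inference: "signature" (default) or "prevalent"
    network_species: str = "signature"

    # --- stage toggles ----------------------------------------------------
    run_diversity: bool = True
    run_signatures: bool = True
    run_da: bool = True
    run_network: bool = True
    run_functional: bool = True

    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.prevalence_threshold <= 1:
            raise ValueError("prevalence_threshold must lie in (0, 1]")
        if not 0 <= self.bootstrap_f <= 1:
            raise ValueError("bootstrap_f must lie in [0, 1]")
        if self.case_group in self.control_groups:
            raise ValueError("case group cannot be among the controls")
        if self.replicate_cap < 1 or self.bootstrap_r < 1 or self.rfc_runs < 2:
            raise ValueError("counts out of domain")
        if not (self.abundance_tsv and self.metadata_tsv) and self.synthetic is None:
            raise ValueError("provide input TSVs or a synthetic recipe")

    # -- serialization ------------------------------------------------------
    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def default_synthetic_config(seed: int = 0, **overrides) -> PipelineConfig:
    """A small three-group synthetic study: one case, internal + external controls."""
    synthetic_recipe = {
        "groups": [
            {"label": "IBD", "n_subjects": 30,
             "replicate_weights": [0.4, 0.2, 0.2, 0.1, 0.1]},
            {"label": "nonIBD", "n_subjects": 25,
             "replicate_weights": [0.4, 0.2, 0.2, 0.1, 0.1]},
            {"label": "Healthy", "n_subjects": 30,
             "replicate_weights": [1.0, 0.0, 0.0, 0.0, 0.0]},
        ],
        "D": 40,
        "sparsity": 0.1,
        "da_spec": [
            ["sp000", "IBD", 2.0],
            ["sp001", "IBD", 2.5],
            ["sp002", "IBD", -2.0],
        ],
        "subject_sd": 0.5,
    }
    cfg = PipelineConfig(synthetic=synthetic_recipe, seed=seed, **overrides)
    return cfg


def _load_cohort(config: PipelineConfig):
    """Materialize the input matrix (from TSVs or the synthetic recipe)."""
    if config.abundance_tsv and config.metadata_tsv:
        return io.read_sample_taxa(config.abundance_tsv, config.metadata_tsv), None
    recipe = dict(config.synthetic)
    groups = [
        synthetic.GroupSpec(
            label=g["label"],
            n_subjects=int(g["n_subjects"]),
            replicate_weights=tuple(g.get("replicate_weights", (1, 0, 0, 0, 0))),
        )
        for g in recipe.pop("groups")
    ]
    da_spec = [tuple(t) for t in recipe.pop("da_spec", [])]
    spec = synthetic.CohortSpec(
        groups=groups,
        da_spec=da_spec,
        noise_floor=config.noise_floor,
        seed=config.seed,
        **recipe,
    )
    matrix, _, truth = synthetic.generate_cohort(spec)
    return matrix, truth


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute all enabled stages and write a reproducible result bundle."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_seeds = {
        name: int(s.generate_state(1)[0] % (2**31 - 1))
        for name, s in zip(
            ("cap", "signatures", "split", "network", "family"),
            np.random.SeedSequence(config.seed).spawn(5),
        )
    }
    summary: dict = {"seed": config.seed, "stage_seeds": stage_seeds}
    results: dict = {}

    matrix, truth = _load_cohort(config)
    if truth is not None:
        truth.to_json(outdir / "truth.json")
    io.write_sample_taxa(matrix, outdir / "abundance.tsv", outdir / "metadata.tsv")
    summary["n_samples_input"] = len(matrix.samples)

    # replicate cap and prevalence filter
    matrix = composition.cap_replicates(matrix, config.replicate_cap, stage_seeds["cap"])
    prevalent = composition.prevalence_filter(matrix, config.prevalence_threshold)
    if len(prevalent) < 2:
        raise RuntimeError("fewer than two prevalent species; nothing to analyse")
    filtered = matrix.select_species(prevalent)
    summary["n_samples"] = len(matrix.samples)
    summary["n_prevalent_species"] = len(prevalent)
    results["matrix"] = matrix
    results["filtered"] = filtered
    results["truth"] = truth

    clr = composition.clr_transform(filtered)
    io.write_dataframe(clr.values, outdir / "clr.tsv", index_label="sample_id")
    results["clr"] = clr

    if config.run_diversity:
        shannon = matrix.abundance.apply(composition.shannon_entropy, axis=1)
        shannon_by_group = shannon.groupby(matrix.groups).median()
        profiles = composition.dissimilarity_profiles(matrix)
        io.write_dataframe(
            shannon.rename("shannon").to_frame(), outdir / "shannon.tsv",
            index_label="sample_id",
        )
        summary["shannon_median_by_group"] = {
            g: round(float(v), 6) for g, v in shannon_by_group.items()
        }
        summary["bcd_medians"] = {
            kind: {g: round(float(np.median(v)), 6) for g, v in profiles[kind].items() if len(v)}
            for kind in ("intrapersonal", "interpersonal")
        }
        results["dissimilarity"] = profiles

    analysis_species = list(filtered.species)
    if config.run_signatures:
        table = signatures.build_feature_table(clr, label_merge=config.label_merge)
        importances = signatures.importance_runs(
            table, R=config.rfc_runs, seed=stage_seeds["signatures"],
            n_trees=config.rfc_trees,
        )
        sig = signatures.significant_features(importances, alpha=config.alpha)
        evaluation = signatures.evaluate_classifier(
            table, train_fraction=config.train_fraction,
            seed=stage_seeds["split"], n_trees=config.rfc_trees,
        )
        io.write_dataframe(sig.table, outdir / "signatures.tsv", index_label="feature")
        io.write_dataframe(evaluation["confusion"], outdir / "confusion.tsv",
                           index_label="true_label")
        sig_species = sig.selected_species(filtered.species)
        summary["n_signature_features"] = len(sig.selected)
        summary["n_signature_species"] = len(sig_species)
        summary["f1_weighted"] = round(evaluation["f1_weighted"], 6)
        summary["f1_per_class"] = {
            c: round(v, 6) for c, v in evaluation["f1_per_class"].items()
        }
        results["signatures"] = sig
        results["evaluation"] = evaluation
        if len(sig_species) >= 2:
            analysis_species = sig_species
    summary["n_analysis_species"] = len(analysis_species)

    da_labels: dict[str, str] = {}
    if config.run_da:
        da_result = da.consensus_da(
            clr.values[analysis_species],
            filtered.abundance[analysis_species],
            filtered.groups,
            config.case_group,
            config.control_groups,
            q_thresh=config.alpha,
            fold_thresh=config.fold_threshold,
        )
        io.write_dataframe(da_result.per_comparison, outdir / "da_comparisons.tsv")
        io.write_dataframe(da_result.consensus, outdir / "da_consensus.tsv",
                           index_label="species")
        da_labels = {
            sp: row["direction"]
            for sp, row in da_result.consensus.iterrows()
            if row["consensus"]
        }
        summary["n_consensus_da"] = len(da_labels)
        summary["n_da_elevated"] = sum(1 for v in da_labels.values() if v == "elevated")
        summary["n_da_depleted"] = sum(1 for v in da_labels.values() if v == "depleted")
        results["da"] = da_result

    if config.run_network:
        net_species = (
            list(filtered.species)
            if config.network_species == "prevalent"
            else analysis_species
        )
        nets: dict[str, network.AssociationNetwork] = {}
        net_seed = np.random.SeedSequence(stage_seeds["network"])
        for group, child in zip(
            sorted(set([config.case_group] + config.control_groups)),
            net_seed.spawn(len(set([config.case_group] + config.control_groups))),
        ):
            block = clr.values.loc[clr.groups == group, net_species]
            if len(block) < 10:
                continue
            sub_seeds = child.spawn(2)
            sel = network.stars_select(
                block,
                lambdas=network.lambda_path(
                    np.cov(block.to_numpy(), rowvar=False, ddof=0), config.n_lambdas
                ),
                subsample_count=config.stars_subsamples,
                beta=config.stars_beta,
                seed=sub_seeds[0],
            )
            est = network.bootstrap_stabilize(
                block, sel["lambda_star"], r=config.bootstrap_r,
                f=config.bootstrap_f, seed=sub_seeds[1],
            )
            net = network.build_network(est)
            nets[group] = net
            io.write_dataframe(net.to_edgelist(), outdir / f"network_{group}.tsv")
            node_table = pd.DataFrame(
                {"degree": net.degree, "evc": net.evc.round(10),
                 "da": [da_labels.get(s, "not_da") for s in net.species]}
            )
            io.write_dataframe(node_table, outdir / f"nodes_{group}.tsv",
                               index_label="species")
        summary["network_edges"] = {
            g: n.graph.number_of_edges() for g, n in nets.items()
        }
        summary["negative_edge_fraction"] = {
            g: round(n.negative_edge_fraction, 6) for g, n in nets.items()
        }
        if config.case_group in nets:
            comparisons = {}
            for g, n in nets.items():
                if g == config.case_group:
                    continue
                rep = network.compare_networks(
                    nets[config.case_group], n, da_labels,
                    names=(config.case_group, g),
                )
                comparisons[g] = {
                    "unique_to_case": rep["n_unique"][config.case_group],
                    "unique_to_control": rep["n_unique"][g],
                    "shared": len(rep["shared_edges"]),
                    "top10_evc_overlap": rep["top_k_overlap"],
                    "case_unique_elevated_fraction": round(
                        rep["unique_edge_elevated_fraction"][config.case_group], 6
                    ),
                }
            summary["network_comparisons"] = comparisons
        results["networks"] = nets

    if config.run_functional:
        counts = synthetic.generate_family_counts(
            list(matrix.species), seed=stage_seeds["family"]
        )
        profile = functional.weight_family_profile(filtered, counts, analysis_species)
        fam_result = functional.family_da(
            profile, config.case_group, config.control_groups,
            q_thresh=config.alpha, fold_thresh=config.fold_threshold,
        )
        roles = functional.aggregate_roles(fam_result, counts.roles)
        io.write_dataframe(fam_result.consensus, outdir / "family_da.tsv",
                           index_label="family")
        io.write_dataframe(roles, outdir / "role_da.tsv")
        summary["n_consensus_families"] = int(fam_result.consensus["consensus"].sum())
        summary["n_da_roles"] = len(roles)
        results["functional"] = fam_result
        results["roles"] = roles

    manifest = {
        "config": asdict(config),
        "stage_seeds": stage_seeds,
        "summary": summary,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    results["summary"] = summary
    return results
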