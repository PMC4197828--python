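"""End-to-end orchestration: simulate or load inputs, then run every stage.

Stages communicate through plain-text files inside one run directory, so
each stage can be re-run on its own (that is what the command-line
interface does).  A manifest records the package version, seeds, the full
parameter set and per-stage counts; runs with identical configuration and
seed produce identical tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._io import read_tsv, write_tsv
from .diffexpr import average_replicates, call_de, mapk_dependence, moderated_test, normalize_table
from .enrich import class_enrichment, classify_kinetics_table, hypergeom_enrichment
from .mixture import MixtureModel, select_K, summarise_clusters, threshold_map_assign
from .motifs import PromoterSet, find_plms, scan_catalog, test_cluster_enrichment
from .network import build_network, hub_report
from .simulate import (
    DEFAULT_COMPARISONS,
    ArrayDesign,
    gen_annotations_and_edges,
    gen_promoters,
    gen_two_colour_arrays,
)

log = logging.getLogger("mapktome")

#: Prototype true profiles over the seven default contrasts, giving the
#: synthetic data a co-expression structure for the clustering stage:
#: flagellin-induced everywhere; induced but attenuated in the mpk4
#: mutant; repressed by flagellin; deregulated only in unchallenged
#: mutants (mpk4, or mpk3 and mpk4 jointly).
DEFAULT_PATTERNS = np.array(
    [
        [2.5, 0.0, 0.0, 0.0, 2.5, 2.5, 2.5],
        [2.5, 0.0, 0.0, 0.0, 2.5, 0.5, 2.5],
        [-2.5, 0.0, 0.0, 0.0, -2.5, -2.5, -2.5],
        [0.0, 0.0, 2.5, 0.0, 0.0, 0.0, 0.0],
        [0.0, 2.5, 2.5, 0.0, 0.0, 0.0, 0.0],
    ]
)

#: Small default catalog: a W-box-like element and an E-box (planted by
#: the simulator) plus unplanted decoys.
DEFAULT_MOTIFS = pd.DataFrame(
    {
        "motif_id": ["wbox", "ebox", "decoy1", "decoy2", "decoy3", "decoy4"],
        "iupac": ["TTGACY", "CACGTG", "GATAAG", "AGTCAA", "CCWACC", "TGTCGG"],
    }
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All thresholds, seeds and switches of the pipeline in one place.

    Threshold defaults: DE call at adjusted p <= 0.05; clustering input
    filtered at Bonferroni p < 0.05; kinase-dependence at a 1 log2-unit
    response difference; misassignment control at 5%; positional-motif
    enrichment at p < 0.01; GO enrichment at p < 0.05; hubs above degree
    19; clusters interpretable above 50% differentially expressed.
    """

    outdir: str = "run"
    seed: int = 0
    simulate: bool = True
    # synthetic scenario
    n_genes: int = 2000
    de_fraction: float = 0.25
    replicates: int = 3
    promoter_length: int = 1000
    n_go_terms: int = 20
    ppi_density: float = 0.004
    tf_target_count: int = 150
    planted_hub_degree: int = 30
    # thresholds
    de_alpha: float = 0.05
    bonferroni_alpha: float = 0.05
    dependence_logratio: float = 1.0
    map_alpha: float = 0.05
    plm_alpha: float = 0.01
    plm_detect_alpha: float = 0.01
    go_alpha: float = 0.05
    hub_cutoff: int = 19
    interpretable_fraction: float = 0.5
    k_min: int = 2
    k_max: int = 40
    # method switches
    null_dist: str = "normal"
    fdr_method: str = "bh"
    strand_mode: str = "both"
    loess_span: float = 0.3
    em_starts: int = 10
    plm_bin_width: int = 50
    # comparison roles
    comparisons: tuple[str, ...] = DEFAULT_COMPARISONS
    reference_comparison: str = DEFAULT_COMPARISONS[0]
    mutant_comparisons: tuple[str, ...] = DEFAULT_COMPARISONS[4:7]
    # external inputs (used when simulate is false)
    probe_table: str | None = None
    promoters_fasta: str | None = None
    motif_catalog: str | None = None
    go_table: str | None = None
    ppi_edges: str | None = None
    tf_edges: str | None = None
    kinetic_reference: str | None = None

    def validate(self) -> None:
        for name in ("de_alpha", "bonferroni_alpha", "map_alpha", "plm_alpha",
                     "plm_detect_alpha", "go_alpha", "interpretable_fraction"):
            value = getattr(self, name)
            if not 0.0 < value < 1.0:
                raise ValueError(f"{name} must lie strictly between 0 and 1, got {value}")
        if self.dependence_logratio <= 0:
            raise ValueError("dependence_logratio must be positive")
        if self.hub_cutoff < 1:
            raise ValueError("hub_cutoff must be >= 1")
        if not 1 <= self.k_min <= self.k_max:
            raise ValueError("need 1 <= k_min <= k_max")
        if self.null_dist not in ("normal", "t"):
            raise ValueError("null_dist must be 'normal' or 't'")
        if self.fdr_method not in ("bonferroni", "bh", "local_fdr"):
            raise ValueError("fdr_method must be bonferroni, bh or local_fdr")
        if self.strand_mode not in ("given", "both"):
            raise ValueError("strand_mode must be 'given' or 'both'")
        if not self.simulate:
            for name in ("probe_table", "promoters_fasta", "motif_catalog",
                         "go_table", "ppi_edges", "tf_edges", "kinetic_reference"):
                path = getattr(self, name)
                if path is None:
                    raise ValueError(f"simulate is false but input path '{name}' is not set")
                if not Path(path).exists():
                    raise ValueError(f"input path '{name}' does not exist: {path}")

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["comparisons"] = list(self.comparisons)
        payload["mutant_comparisons"] = list(self.mutant_comparisons)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        for key in ("comparisons", "mutant_comparisons"):
            if key in payload and payload[key] is not None:
                payload[key] = tuple(payload[key])
        return cls(**payload)


def percent(k: int, n: int) -> int:
    """Integer percentage as printed in summary tables: round(100 k / n)."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    return int(round(100.0 * k / n))


@dataclass
class Pipeline:
    """Runs the stages in order inside ``config.outdir``."""

    config: PipelineConfig
    counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.config.validate()
        self.out = Path(self.config.outdir)
        self.out.mkdir(parents=True, exist_ok=True)
        self._seeds = {
            name: int(ss.generate_state(1)[0] % (2**31 - 1))
            for name, ss in zip(
                ("arrays", "promoters", "annotations", "kinetics", "cluster"),
                np.random.SeedSequence(self.config.seed).spawn(5),
            )
        }

    # -- helpers -----------------------------------------------------------
    def _path(self, name: str) -> Path:
        return self.out / name

    def _input(self, key: str, simulated_name: str) -> Path:
        if self.config.simulate:
            return self._path(simulated_name)
        return Path(getattr(self.config, key))

    def _run(self, name, fn):
        log.info("stage %s: start", name)
        try:
            fn()
        except Exception as err:  # keep upstream outputs, name the stage
            raise PipelineError(name, err) from err
        log.info("stage %s: done %s", name, self.counts.get(name, ""))

    # -- stages ------------------------------------------------------------
    def stage_simulate(self) -> None:
        cfg = self.config
        design = ArrayDesign(
            comparisons=cfg.comparisons, replicates_per_comparison=cfg.replicates
        )
        table, truth = gen_two_colour_arrays(
            design,
            cfg.n_genes,
            de_fraction=cfg.de_fraction,
            seed=self._seeds["arrays"],
            patterns=DEFAULT_PATTERNS[:, : len(cfg.comparisons)],
        )
        write_tsv(table, self._path("probe_table.tsv"))
        write_tsv(truth.true_logratio.reset_index(names="gene_id"), self._path("truth_logratio.tsv"))
        write_tsv(
            truth.cluster_labels.rename("cluster").rename_axis("gene_id").reset_index(),
            self._path("truth_clusters.tsv"),
        )
        labels = truth.cluster_labels
        pattern0 = list(labels.index[labels == 0])
        pattern3 = list(labels.index[labels == 3])
        promoters, ptruth = gen_promoters(
            cfg.n_genes,
            length=cfg.promoter_length,
            planted=[
                ("TTGACY", pattern0, (-300, -200), 0.8),
                ("CACGTG", pattern3, (-650, -550), 0.8),
            ],
            seed=self._seeds["promoters"],
        )
        promoters.to_fasta(self._path("promoters.fasta"))
        write_tsv(DEFAULT_MOTIFS, self._path("motif_catalog.tsv"))
        write_tsv(
            pd.DataFrame(
                [{"motif": m, "window_start": w[0], "window_end": w[1]}
                 for m, w in ptruth.motif_windows.items()]
            ),
            self._path("truth_motif_windows.tsv"),
        )
        genes = list(labels.index)
        # hubs live among the co-expressed genes and connect within them,
        # mirroring a network restricted to the clustered gene universe
        pattern_genes = list(labels.index[labels >= 0])
        rng = np.random.default_rng(self._seeds["annotations"])
        hub_genes = list(rng.choice(pattern_genes, size=3, replace=False))
        go, ppi, tf = gen_annotations_and_edges(
            cfg.n_genes,
            n_terms=cfg.n_go_terms,
            ppi_density=cfg.ppi_density,
            tf_target_count=cfg.tf_target_count,
            planted_hubs=[(g, cfg.planted_hub_degree) for g in hub_genes],
            seed=self._seeds["annotations"],
            hub_partner_pool=pattern_genes,
        )
        # one planted term concentrated in the first prototype group
        planted_term = pd.DataFrame({"gene_id": pattern0, "term_id": "GO:planted"})
        go = pd.concat([go, planted_term], ignore_index=True).drop_duplicates()
        write_tsv(go, self._path("go.tsv"))
        write_tsv(ppi, self._path("edges_ppi.tsv"))
        write_tsv(tf, self._path("edges_tf.tsv"))
        write_tsv(pd.DataFrame({"gene_id": hub_genes}), self._path("truth_hubs.tsv"))
        # kinetic reference: first group early-induced, fourth group late
        krng = np.random.default_rng(self._seeds["kinetics"])
        fc1 = np.exp(krng.normal(0.0, 0.2, size=cfg.n_genes))
        fc3 = np.exp(krng.normal(0.0, 0.2, size=cfg.n_genes))
        gene_pos = {g: i for i, g in enumerate(genes)}
        for g in pattern0:
            fc1[gene_pos[g]] *= 8.0
            fc3[gene_pos[g]] *= 6.0
        for g in pattern3:
            fc3[gene_pos[g]] *= 8.0
        write_tsv(
            pd.DataFrame({"gene_id": genes, "fc_1h": fc1, "fc_3h": fc3}),
            self._path("kinetics.tsv"),
        )
        self.counts["simulate"] = {
            "n_genes": cfg.n_genes,
            "n_probe_rows": len(table),
            "planted_hubs": hub_genes,
        }

    def stage_normalize(self) -> None:
        table = read_tsv(self._input("probe_table", "probe_table.tsv"))
        norm = normalize_table(table, span=self.config.loess_span)
        write_tsv(norm, self._path("normalized.tsv"))
        self.counts["normalize"] = {"n_hybridisations": int(
            norm.groupby(["comparison", "bio_rep", "dye_swap"]).ngroups)}

    def stage_de(self) -> None:
        cfg = self.config
        norm = read_tsv(self._path("normalized.tsv"))
        design = ArrayDesign(comparisons=cfg.comparisons, replicates_per_comparison=cfg.replicates)
        matrix = average_replicates(norm, design)
        mean = matrix.mean
        write_tsv(mean.reset_index(names="gene_id"), self._path("logratio_mean.tsv"))
        reps = matrix.replicates.copy()
        reps.columns = [f"{c}|{r}" for c, r in reps.columns]
        write_tsv(reps.reset_index(names="gene_id"), self._path("logratio_replicates.tsv"))
        tests = moderated_test(matrix, null=cfg.null_dist)
        de = call_de(tests, alpha=cfg.de_alpha, fdr_method=cfg.fdr_method)
        write_tsv(de, self._path("de_results.tsv"))
        counts = (
            de[de["de_flag"]]
            .assign(direction=lambda t: np.where(t["logratio"] > 0, "genes_up", "genes_down"))
            .groupby(["comparison", "direction"])
            .size()
            .unstack(fill_value=0)
            .reindex(columns=["genes_up", "genes_down"], fill_value=0)
            .reindex(list(cfg.comparisons), fill_value=0)
            .reset_index()
        )
        write_tsv(counts, self._path("de_counts.tsv"))
        prior = tests.attrs["prior"]
        self.counts["de"] = {
            "prior_d0": float(prior.d0),
            "prior_s0_sq": float(prior.s0_sq),
            "de_counts": counts.set_index("comparison").to_dict("index"),
        }

    def stage_depend(self) -> None:
        cfg = self.config
        de = read_tsv(self._path("de_results.tsv"))
        mean = read_tsv(self._path("logratio_mean.tsv")).set_index("gene_id")
        ref_flags = (
            de[de["comparison"] == cfg.reference_comparison]
            .set_index("gene_id")["de_flag"]
        )
        dep = mapk_dependence(
            mean, ref_flags, cfg.reference_comparison, list(cfg.mutant_comparisons),
            threshold=cfg.dependence_logratio,
        )
        write_tsv(dep, self._path("dependence.tsv"))
        affected_any = dep[dep["status"] == "affected"]["gene_id"].nunique()
        n_ref = int(ref_flags.sum())
        self.counts["depend"] = {
            "n_regulated_reference": n_ref,
            "n_affected_any_mutant": int(affected_any),
            "pct_affected": percent(affected_any, n_ref) if n_ref else None,
        }

    def stage_cluster(self) -> None:
        cfg = self.config
        de = read_tsv(self._path("de_results.tsv"))
        mean = read_tsv(self._path("logratio_mean.tsv")).set_index("gene_id")
        bonf = de.pivot(index="gene_id", columns="comparison", values="p_bonf")
        bonf = bonf.reindex(index=mean.index, columns=mean.columns)
        selected = bonf.lt(cfg.bonferroni_alpha).any(axis=1)
        X = mean.loc[selected]
        if len(X) == 0:
            raise ValueError("no rows pass the Bonferroni filter; nothing to cluster")
        model, trace = select_K(
            X.to_numpy(),
            K_range=range(cfg.k_min, cfg.k_max + 1),
            n_starts=cfg.em_starts,
            seed=self._seeds["cluster"],
        )
        model.to_json(self._path("model.json"))
        write_tsv(trace, self._path("bic_trace.tsv"))
        assignment = threshold_map_assign(model, X.to_numpy(), alpha=cfg.map_alpha, index=X.index)
        out = assignment.table.reset_index(names="gene_id")
        write_tsv(out, self._path("assignments.tsv"))
        de_flags = bonf.loc[X.index].lt(cfg.bonferroni_alpha)
        profiles, clusters = summarise_clusters(
            assignment, X, de_flags, interpretable_fraction=cfg.interpretable_fraction
        )
        write_tsv(profiles, self._path("cluster_profiles.tsv"))
        write_tsv(clusters, self._path("cluster_table.tsv"))
        self.counts["cluster"] = {
            "n_filtered": int(selected.sum()),
            "K": model.K,
            "tau": assignment.tau,
            "n_classified": assignment.n_classified,
            "expected_misassigned": assignment.expected_misassigned,
            "n_interpretable": int(clusters["interpretable"].sum()),
        }

    def _cluster_members(self) -> dict[int, list[str]]:
        assign = read_tsv(self._path("assignments.tsv"))
        members = assign[assign["classified"]]
        return {int(c): sub["gene_id"].tolist() for c, sub in members.groupby("label")}

    def stage_plm(self) -> None:
        cfg = self.config
        promoters = PromoterSet.from_fasta(self._input("promoters_fasta", "promoters.fasta"))
        catalog = read_tsv(self._input("motif_catalog", "motif_catalog.tsv"))
        occurrences = scan_catalog(promoters, catalog, strands=cfg.strand_mode)
        write_tsv(occurrences, self._path("occurrences.tsv"))
        plms, occ_by_motif = find_plms(
            promoters, catalog, strands=cfg.strand_mode,
            bin_width=cfg.plm_bin_width, alpha_detect=cfg.plm_detect_alpha,
        )
        write_tsv(
            pd.DataFrame(
                [
                    {"motif_id": r.motif_id, "window_start": r.window[0],
                     "window_end": r.window[1],
                     "genome_genes": r.genome_genes_with_hit_in_window,
                     "genome_total": r.genome_total, "pvalue": r.pvalue}
                    for r in plms.values()
                ],
                columns=["motif_id", "window_start", "window_end",
                         "genome_genes", "genome_total", "pvalue"],
            ),
            self._path("plms.tsv"),
        )
        rows = []
        for cluster, genes in self._cluster_members().items():
            genes_in = [g for g in genes if g in promoters]
            if not genes_in:
                continue
            for motif_id, record in plms.items():
                res = test_cluster_enrichment(
                    record, genes_in, occ_by_motif[motif_id],
                    alpha=cfg.plm_alpha, cluster_id=str(cluster),
                )
                rows.append(dataclasses.asdict(res))
        enrichment = pd.DataFrame(
            rows, columns=["cluster_id", "motif_id", "k", "n", "p0", "pvalue", "significant"]
        )
        write_tsv(enrichment, self._path("plm_enrichment.tsv"))
        self.counts["plm"] = {
            "n_plms": len(plms),
            "n_enriched": int(enrichment["significant"].sum()) if len(enrichment) else 0,
        }

    def stage_go(self) -> None:
        cfg = self.config
        go = read_tsv(self._input("go_table", "go.tsv"))
        mean = read_tsv(self._path("logratio_mean.tsv"))
        universe = mean["gene_id"].tolist()
        rows = []
        for cluster, genes in self._cluster_members().items():
            res = hypergeom_enrichment(genes, go, universe, alpha=cfg.go_alpha)
            res.insert(0, "cluster", cluster)
            rows.append(res)
        result = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
        write_tsv(result, self._path("go_enrichment.tsv"))
        self.counts["go"] = {
            "n_significant": int(result["significant"].sum()) if len(result) else 0
        }

    def stage_kinetics(self) -> None:
        cfg = self.config
        reference = read_tsv(self._input("kinetic_reference", "kinetics.tsv"))
        classes = classify_kinetics_table(reference)
        write_tsv(
            classes.rename("kinetic_class").rename_axis("gene_id").reset_index(),
            self._path("kinetic_classes.tsv"),
        )
        rows = []
        for cluster, genes in self._cluster_members().items():
            res = class_enrichment(genes, classes, alpha=cfg.go_alpha)
            res.insert(0, "cluster", cluster)
            rows.append(res)
        result = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
        write_tsv(result, self._path("kinetic_enrichment.tsv"))
        self.counts["kinetics"] = {
            "n_classified_genes": int((classes != "unclassified").sum()),
            "n_significant": int(result["significant"].sum()) if len(result) else 0,
        }

    def stage_network(self) -> None:
        cfg = self.config
        ppi = read_tsv(self._input("ppi_edges", "edges_ppi.tsv"))
        tf = read_tsv(self._input("tf_edges", "edges_tf.tsv"))
        universe = {g for genes in self._cluster_members().values() for g in genes}
        graph = build_network(ppi, tf, universe)
        if graph.graph.number_of_nodes() == 0:
            self.counts["network"] = {"n_nodes": 0, "n_edges": 0, "n_hubs": 0}
            write_tsv(pd.DataFrame(columns=["node", "degree", "hub"]), self._path("degrees.tsv"))
            return
        table, summary = hub_report(graph, hub_cutoff=cfg.hub_cutoff)
        graph.to_sif(self._path("network.sif"))
        graph.to_graphml(self._path("network.graphml"))
        write_tsv(table, self._path("degrees.tsv"))
        self.counts["network"] = summary

    # -- drivers -----------------------------------------------------------
    STAGES = ("simulate", "normalize", "de", "depend", "cluster",
              "plm", "go", "kinetics", "network")

    def run_all(self) -> dict:
        for stage in self.STAGES:
            if stage == "simulate" and not self.config.simulate:
                continue
            self._run(stage, getattr(self, f"stage_{stage}"))
        manifest = self.write_manifest()
        self.make_report()
        return manifest

    def write_manifest(self) -> dict:
        cfg = dataclasses.asdict(self.config)
        cfg["comparisons"] = list(self.config.comparisons)
        cfg["mutant_comparisons"] = list(self.config.mutant_comparisons)
        manifest = {
            "package": "mapktome",
            "version": __version__,
            "seed": self.config.seed,
            "stage_seeds": self._seeds,
            "config": cfg,
            "counts": self.counts,
        }
        with open(self._path("manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        return manifest

    # -- report ------------------------------------------------------------
    def recovery_metrics(self) -> dict | None:
        """Compare pipeline output against simulation truth, when present."""
        truth_lr = self._path("truth_logratio.tsv")
        if not truth_lr.exists():
            return None
        metrics: dict = {}
        truth = read_tsv(truth_lr).set_index("gene_id")
        mean = read_tsv(self._path("logratio_mean.tsv")).set_index("gene_id")
        common = truth.index.intersection(mean.index)
        err = (mean.loc[common, truth.columns] - truth.loc[common]).to_numpy()
        metrics["effect_rmse"] = float(np.sqrt(np.mean(err**2)))
        labels_path = self._path("truth_clusters.tsv")
        assign_path = self._path("assignments.tsv")
        if labels_path.exists() and assign_path.exists():
            from sklearn.metrics import adjusted_rand_score

            truth_labels = read_tsv(labels_path).set_index("gene_id")["cluster"]
            assign = read_tsv(assign_path).set_index("gene_id")
            classified = assign[assign["classified"]]
            shared = classified.index.intersection(truth_labels.index)
            if len(shared):
                metrics["ari_classified"] = float(
                    adjusted_rand_score(truth_labels.loc[shared], classified.loc[shared, "label"])
                )
        windows_path = self._path("truth_motif_windows.tsv")
        plms_path = self._path("plms.tsv")
        if windows_path.exists() and plms_path.exists():
            planted = read_tsv(windows_path)
            plms = read_tsv(plms_path)
            overlaps = []
            catalog = read_tsv(self._input("motif_catalog", "motif_catalog.tsv"))
            iupac_to_id = dict(zip(catalog["iupac"], catalog["motif_id"]))
            for _, row in planted.iterrows():
                motif_id = iupac_to_id.get(row["motif"])
                hit = plms[plms["motif_id"] == motif_id]
                if len(hit) == 0:
                    overlaps.append(0.0)
                    continue
                a = max(row["window_start"], int(hit.iloc[0]["window_start"]))
                b = min(row["window_end"], int(hit.iloc[0]["window_end"]))
                width = row["window_end"] - row["window_start"] + 1
                overlaps.append(max(0, b - a + 1) / width)
            if overlaps:
                metrics["plm_window_overlap"] = float(np.mean(overlaps))
        hubs_path = self._path("truth_hubs.tsv")
        degrees_path = self._path("degrees.tsv")
        if hubs_path.exists() and degrees_path.exists():
            planted_hubs = set(read_tsv(hubs_path)["gene_id"])
            degrees = read_tsv(degrees_path)
            called = set(degrees[degrees["hub"]]["node"]) if len(degrees) else set()
            if planted_hubs:
                metrics["hub_recall"] = len(planted_hubs & called) / len(planted_hubs)
        return metrics

    def make_report(self) -> str:
        """Summarise the run's outputs into a markdown report."""
        lines = ["# mapktome run report", ""]
        counts_path = self._path("de_counts.tsv")
        if counts_path.exists():
            lines += ["## Number of differentially expressed genes", ""]
            counts = read_tsv(counts_path)
            lines += [counts.to_markdown(index=False), ""]
        else:
            lines += ["(differential expression stage missing)", ""]
        clusters_path = self._path("cluster_table.tsv")
        if clusters_path.exists():
            clusters = read_tsv(clusters_path)
            n_interp = int(clusters["interpretable"].sum())
            lines += [
                "## Co-expression clusters",
                "",
                f"{len(clusters)} clusters with classified members; "
                f"{n_interp} interpretable (>50% differentially expressed "
                f"in some comparison)."
                if n_interp
                else f"{len(clusters)} clusters; zero interpretable clusters.",
                "",
                clusters.to_markdown(index=False),
                "",
            ]
            profiles_path = self._path("cluster_profiles.tsv")
            if profiles_path.exists():
                lines += ["### Cluster profiles (boxplot summaries)", "",
                          read_tsv(profiles_path).round(3).to_markdown(index=False), ""]
        else:
            lines += ["## Co-expression clusters", "",
                      "zero interpretable clusters (stage missing or empty)", ""]
        for title, name in (
            ("Positional motif enrichment", "plm_enrichment.tsv"),
            ("GO enrichment", "go_enrichment.tsv"),
            ("Kinetic class enrichment", "kinetic_enrichment.tsv"),
        ):
            path = self._path(name)
            if path.exists():
                table = read_tsv(path)
                hits = table[table["significant"]] if "significant" in table else table
                lines += [f"## {title}", "",
                          hits.to_markdown(index=False) if len(hits) else "no significant entries",
                          ""]
        if "network" in self.counts:
            lines += ["## Interaction network", "",
                      json.dumps(self.counts["network"]), ""]
        metrics = self.recovery_metrics()
        if metrics:
            lines += ["## Recovery against simulation truth", "",
                      json.dumps(metrics, indent=1), ""]
        report = "\n".join(lines)
        self._path("report.md").write_text(report)
        return report


def run_all(config: PipelineConfig) -> dict:
    """Convenience wrapper: build a :class:`Pipeline` and run every stage."""
    return Pipeline(config).run_all()
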