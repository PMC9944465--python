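"""End-to-end orchestration: simulate-or-load, quantify, QC, cluster,
differential test, kinase consensus, network, enrichment, outcomes.

Every stage writes a tidy CSV/TSV into the output directory and the run ends
with a JSON manifest of per-stage counts.  Stages whose inputs are absent
(e.g. no clinical table) are skipped with a logged notice.  A rerun with the
same config and seed reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import clinical as clin
from . import enrichment as enr
from . import io as kio
from . import kinases as kin
from . import network as net
from . import profiling as prof
from . import quantify as qt
from .simulate import SimulationConfig, generate_kinome_dataset, generate_reference_fixtures

logger = logging.getLogger("kinact")

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]


@dataclass
class PipelineConfig:
    """One config object driving the whole analysis.

    Exactly one of ``simulation`` (a :class:`SimulationConfig`) or ``inputs``
    (a mapping of paths: intensity_csv, annotations_a, annotations_b,
    edges_tsv, pathways_gmt, clinical_csv; any subset) must be provided.
    """

    outdir: str | Path = "kinact_out"
    simulation: SimulationConfig | None = None
    inputs: dict[str, str] | None = None
    floor_epsilon: float = 1e-3
    qc_rule: str = "median"
    qc_threshold: float = 0.0
    linkage: str = "average"
    k_peptides: int = 3
    k_samples: int = 2
    alpha: float = 0.05
    hub_fraction: float = 0.10
    bottleneck_count: int = 10
    min_confidence: float = 0.4
    p_cutoff: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if (self.simulation is None) == (self.inputs is None):
            raise ValueError("exactly one of {simulation, inputs} must be set")
        for name, value, lo in [
            ("floor_epsilon", self.floor_epsilon, 0.0),
            ("hub_fraction", self.hub_fraction, 0.0),
        ]:
            if value <= lo:
                raise ValueError(f"{name} must be > {lo}")
        for name, value in [
            ("k_peptides", self.k_peptides),
            ("k_samples", self.k_samples),
            ("bottleneck_count", self.bottleneck_count),
        ]:
            if value is None or int(value) < 2 and name != "bottleneck_count":
                raise ValueError(f"{name} missing or out of range")
        if not 0 < self.alpha < 1 or not 0 < self.p_cutoff < 1:
            raise ValueError("alpha and p_cutoff must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in {f.name for f in dataclasses.fields(cls)}})
        if sim is not None:
            cfg.simulation = SimulationConfig(**sim)
        return cfg

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["outdir"] = str(self.outdir)
        if self.simulation is not None:
            d["simulation"] = dataclasses.asdict(self.simulation)
            d["simulation"]["response_probs"] = dict(self.simulation.response_probs)
        # tuples -> lists so the dict is YAML/JSON-safe
        return json.loads(json.dumps(d, default=str))

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    counts: dict[str, int] = field(default_factory=dict)
    files: dict[str, str] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)
    timestamp: float = 0.0

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True))

    def comparable(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("timestamp")
        return d


def run_pipeline(config: PipelineConfig) -> RunManifest:
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.content_hash(), timestamp=time.time())

    def emit(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        manifest.files[name] = name

    # ------------------------------------------------------------------ input
    annotations_a = annotations_b = edges = pathways = clinical_table = None
    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        intensity, clinical_table, truth = generate_kinome_dataset(sim)
        annotations_a, annotations_b, edges, pathways = generate_reference_fixtures(sim)
        emit("intensities.csv", lambda p: kio.write_intensity_table(intensity, p))
        emit("clinical.csv", lambda p: kio.write_clinical_table(clinical_table, p))
        emit("ground_truth.json", truth.to_json)
    else:
        paths = dict(config.inputs or {})
        intensity = kio.read_intensity_table(paths["intensity_csv"])
        aliases = kin.load_aliases()
        if "annotations_a" in paths and "annotations_b" in paths:
            annotations_a = kio.read_kinase_db(paths["annotations_a"], "source_a", aliases)
            annotations_b = kio.read_kinase_db(paths["annotations_b"], "source_b", aliases)
        if "edges_tsv" in paths:
            edges = kio.read_edge_list(paths["edges_tsv"], config.min_confidence)
        if "pathways_gmt" in paths:
            pathways = kio.read_gmt(paths["pathways_gmt"])
        if "clinical_csv" in paths:
            clinical_table = kio.read_clinical_table(paths["clinical_csv"])
    manifest.counts["peptides_in"] = len(intensity.peptide_ids)

    # --------------------------------------------------------- quantification
    slopes = qt.fit_slope_table(intensity)
    qc = qt.qc_filter_peptides(slopes, rule=config.qc_rule, threshold=config.qc_threshold)
    retained = [p for p in slopes.index if p in qc.retained_peptides]
    manifest.counts["peptides_retained"] = len(retained)
    emit(
        "qc_report.tsv",
        lambda p: pd.DataFrame(
            {
                "peptide_id": list(slopes.index),
                "retained": [pep in qc.retained_peptides for pep in slopes.index],
                "reason": [qc.reason.get(pep, "") for pep in slopes.index],
            }
        ).to_csv(p, sep="\t", index=False),
    )
    activity = qt.log2_transform_slopes(slopes.loc[retained], config.floor_epsilon)
    matrix = qt.average_duplicates(activity)
    emit("activity_matrix.csv", lambda p: matrix.values.to_csv(p, float_format="%.8g"))

    # -------------------------------------------------------------- profiling
    pep_clusters = prof.label_peptide_clusters(
        matrix, prof.cluster_matrix(matrix, "peptides", config.k_peptides, config.linkage)
    ) if config.k_peptides == 3 else prof.cluster_matrix(
        matrix, "peptides", config.k_peptides, config.linkage
    )
    smp_clusters = prof.label_sample_clusters(
        matrix, prof.cluster_matrix(matrix, "samples", config.k_samples, config.linkage)
    ) if config.k_samples == 2 else prof.cluster_matrix(
        matrix, "samples", config.k_samples, config.linkage
    )
    emit(
        "peptide_clusters.csv",
        lambda p: pd.Series(pep_clusters.labels, name="cluster")
        .rename_axis("peptide_id")
        .to_csv(p),
    )
    emit(
        "sample_clusters.csv",
        lambda p: pd.Series(smp_clusters.labels, name="cluster").rename_axis("sample").to_csv(p),
    )
    emit(
        "heatmap_matrix.csv",
        lambda p: matrix.values.loc[pep_clusters.leaf_order, smp_clusters.leaf_order].to_csv(
            p, float_format="%.8g"
        ),
    )
    diff = prof.differential_table(matrix, smp_clusters, alpha=config.alpha)
    manifest.counts["significant_peptides"] = int(diff["significant"].sum())
    emit("differential.csv", lambda p: diff.to_csv(p, index=False, float_format="%.8g"))
    significant = list(diff.loc[diff["significant"], "peptide_id"])

    # -------------------------------------------------------- kinase consensus
    if annotations_a is not None and annotations_b is not None:
        aliases = kin.load_aliases()
        annotated_peps = [
            p
            for p in retained
            if annotations_a.get(p) is not None or annotations_b.get(p) is not None
        ]
        calls = kin.consensus_table(annotated_peps, annotations_a, annotations_b, aliases)
        emit(
            "consensus_kinases.csv",
            lambda p: pd.DataFrame(
                {
                    "peptide_id": [c.peptide.raw for c in calls],
                    "source_a": [",".join(sorted(c.source_a_kinases)) for c in calls],
                    "source_b": [",".join(sorted(c.source_b_kinases)) for c in calls],
                    "consensus": [",".join(sorted(c.consensus)) for c in calls],
                }
            ).to_csv(p, index=False),
        )
        kin_universe = set().union(*(c.consensus for c in calls)) if calls else set()
        manifest.counts["consensus_kinases"] = len(kin_universe)
        venn = kin.venn_partition(calls, pep_clusters.labels)
        emit(
            "venn_regions.csv",
            lambda p: pd.DataFrame(
                [
                    {"region": "+".join(sorted(region)), "kinases": ",".join(sorted(ks))}
                    for region, ks in sorted(
                        venn.regions.items(), key=lambda kv: sorted(kv[0])
                    )
                ]
            ).to_csv(p, index=False),
        )
    else:
        manifest.skipped.append("kinase_consensus")
        logger.info("no annotation sources; skipping kinase consensus")

    # ----------------------------------------------------------------- network
    query_proteins = {kin.parse_peptide_id(p).protein for p in significant}
    if edges is not None and query_proteins:
        ppi = net.build_ppi_network(edges, restrict_to=query_proteins | set())
        cent = net.node_centralities(ppi)
        hb = net.identify_hub_bottlenecks(
            cent, ppi, hub_fraction=config.hub_fraction, bottleneck_count=config.bottleneck_count
        )
        manifest.counts["network_nodes"] = ppi.graph.number_of_nodes()
        manifest.counts["network_edges"] = ppi.n_edges
        manifest.counts["hubs"] = len(hb.hubs)
        manifest.counts["bottlenecks"] = len(hb.bottlenecks)
        manifest.counts["hub_bottlenecks"] = len(hb.hub_bottlenecks)
        emit("centrality.csv", lambda p: cent.to_csv(p, index=False, float_format="%.8g"))
        emit(
            "hub_bottlenecks.csv",
            lambda p: pd.DataFrame(
                {
                    "node": hb.hub_bottlenecks,
                    "role": ["hub_bottleneck"] * len(hb.hub_bottlenecks),
                }
            ).to_csv(p, index=False),
        )
    else:
        manifest.skipped.append("network")
        logger.info("no edge list or no significant proteins; skipping network analysis")

    # -------------------------------------------------------------- enrichment
    if pathways is not None and query_proteins & set(pathways.universe):
        table = enr.enrichment_table(
            query_proteins & set(pathways.universe), pathways, p_cutoff=config.p_cutoff
        )
        manifest.counts["enriched_pathways"] = int(table["significant"].sum()) if len(table) else 0
        emit("enrichment.csv", lambda p: table.to_csv(p, index=False, float_format="%.8g"))
        emit(
            "enrichment_dotplot.csv",
            lambda p: table[["pathway_id", "gene_ratio", "q_value", "observed"]].to_csv(
                p, index=False, float_format="%.8g"
            ),
        )
    else:
        manifest.skipped.append("enrichment")
        logger.info("no pathway collection or unmapped query; skipping enrichment")

    # ---------------------------------------------------------------- outcomes
    if clinical_table is not None:
        summary = clin.response_rates(clinical_table)
        emit(
            "response_summary.csv",
            lambda p: pd.DataFrame([summary.as_row()]).to_csv(p, index=False),
        )
        case_groups = {c: smp_clusters.labels.get(c) for c in clinical_table.case_ids}
        if all(g is not None for g in case_groups.values()) and len(set(case_groups.values())) == 2:
            df = clinical_table.data
            rows = []
            for endpoint in ("pfs", "os"):
                g1 = df[df["case_id"].map(case_groups) == "1"]
                g2 = df[df["case_id"].map(case_groups) == "2"]
                res = clin.logrank_and_hr(
                    (g1[f"{endpoint}_months"], g1[f"{endpoint}_event"]),
                    (g2[f"{endpoint}_months"], g2[f"{endpoint}_event"]),
                    alpha=config.alpha,
                )
                rows.append(
                    {
                        "endpoint": endpoint.upper(),
                        "chi_square": res.chi_square,
                        "p_value": res.p_value,
                        "hazard_ratio": res.hazard_ratio,
                        "ci_low": res.ci_low,
                        "ci_high": res.ci_high,
                        "median_group1": res.median_by_group[0],
                        "median_group2": res.median_by_group[1],
                    }
                )
                for gi, sub in (("1", g1), ("2", g2)):
                    km = clin.kaplan_meier(sub[f"{endpoint}_months"], sub[f"{endpoint}_event"])
                    curve = pd.DataFrame(
                        {
                            "time": km.event_times,
                            "at_risk": km.at_risk,
                            "n_events": km.n_events,
                            "survival": km.survival,
                        }
                    )
                    emit(
                        f"km_{endpoint}_group{gi}.csv",
                        lambda p, c=curve: c.to_csv(p, index=False, float_format="%.8g"),
                    )
            emit(
                "logrank.csv",
                lambda p: pd.DataFrame(rows).to_csv(p, index=False, float_format="%.8g"),
            )
        else:
            manifest.skipped.append("survival_comparison")
            logger.info("cases not covered by 2 sample clusters; skipping survival comparison")
    else:
        manifest.skipped.append("clinical_outcomes")
        logger.info("no clinical table; skipping outcome statistics")

    manifest.write(outdir / "manifest.json")
    return manifest
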