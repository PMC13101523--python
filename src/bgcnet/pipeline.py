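"""Stage orchestration: genomic and metabolomic runs from a config mapping.

The config is a flat declarative mapping (usually loaded from YAML) whose
defaults are the survey's printed parameters: clustering and novelty
thresholds of 0.2 on cosine distance, and network thresholds of cosine
0.70, 6 matched peaks, 0.02 Da tolerances, top-K 10 and a component cap of
100.  Reports are plain TSV/JSON/GraphML files without timestamps, so a
rerun on unchanged inputs is byte-identical; each report directory carries
the config echo for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import bgc_io, features, gcf_cluster, masscalc, novelty, specnet

log = logging.getLogger("bgcnet")

CONFIG_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    collections: dict[str, str] = field(default_factory=dict)  # label -> domain table TSV
    taxonomy: str | None = None
    reference_collections: dict[str, str] = field(default_factory=dict)
    spectra: str | None = None
    blanks: str | None = None
    feature_mode: str = "bitscore"
    clustering_threshold: float = 0.2
    novelty_threshold: float = 0.2
    novelty_method: str = "member-mean"
    min_cosine: float = 0.70
    min_matched: int = 6
    frag_tol: float = 0.02
    prec_tol: float = 0.02
    top_k: int = 10
    max_component: int = 100
    mass_checks: list[dict] = field(default_factory=list)
    out_dir: str = "bgcnet_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        version = raw.pop("schema_version", CONFIG_SCHEMA_VERSION)
        if version != CONFIG_SCHEMA_VERSION:
            raise ValueError(f"unsupported config schema_version {version}")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def echo(self) -> dict:
        payload = {k: getattr(self, k) for k in self.__dataclass_fields__}
        payload["schema_version"] = CONFIG_SCHEMA_VERSION
        blob = json.dumps(payload, sort_keys=True)
        payload["config_sha256"] = hashlib.sha256(blob.encode()).hexdigest()
        return payload

    def network_params(self) -> specnet.NetworkParams:
        return specnet.NetworkParams(
            min_cosine=self.min_cosine,
            min_matched=self.min_matched,
            frag_tol=self.frag_tol,
            prec_tol=self.prec_tol,
            top_k=self.top_k,
            max_component=self.max_component,
        )


def _write_json(payload: dict, path: Path) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def run_genomic(config: RunConfig) -> dict:
    """Collections -> features -> GCFs -> novelty/Venn reports.

    All focal collections are pooled into one vocabulary and clustered
    together; each declared reference collection scores the focal GCFs'
    d- statistic separately.
    """
    if not config.collections:
        raise ValueError("config key 'collections' is empty: map label -> domain-table TSV")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    focal: list[bgc_io.BGCRecord] = []
    for label, path in sorted(config.collections.items()):
        if not Path(path).exists():
            raise FileNotFoundError(f"config collections[{label!r}]: no such file {path}")
        recs = bgc_io.parse_domain_table(path)
        for r in recs:
            r.collection = label
        focal.extend(recs)
        log.info("collection %s: %d BGCs", label, len(recs))
    references: dict[str, list[bgc_io.BGCRecord]] = {}
    for label, path in sorted(config.reference_collections.items()):
        if not Path(path).exists():
            raise FileNotFoundError(f"config reference_collections[{label!r}]: no such file {path}")
        references[label] = bgc_io.parse_domain_table(path)

    pooled = focal + [r for recs in references.values() for r in recs]
    vocab = features.build_vocabulary(pooled)
    ids, vecs = features.feature_matrix(focal, vocab, config.feature_mode)
    dist = features.pairwise_distances(vecs, ids)
    partition = gcf_cluster.average_linkage_cluster(dist, config.clustering_threshold)
    gcfs = gcf_cluster.build_gcfs(partition, focal, dist)
    gcf_cluster.write_partition_tsv(partition, gcfs, out / "gcf_partition.tsv")
    log.info("clustered %d BGCs into %d GCFs", len(focal), len(gcfs))

    vectors_by_bgc = dict(zip(ids, vecs))
    novelty_summary = {}
    for label, recs in references.items():
        _, ref_vecs = features.feature_matrix(recs, vocab, config.feature_mode)
        scores = novelty.score_gcfs(
            gcfs, vectors_by_bgc, ref_vecs, label,
            config.novelty_threshold, config.novelty_method,
        )
        novelty.write_novelty_tsv(scores, out / f"novelty_{label}.tsv")
        n_novel, pct = novelty.novelty_report(scores)
        novelty_summary[label] = {"n_novel": n_novel, "pct_novel": pct, "n_gcfs": len(scores)}

    venn = novelty.venn_partition(gcfs)
    venn.to_json(out / "venn.json")

    summary_report = None
    if config.taxonomy:
        taxonomy = bgc_io.TaxonomyTable.read_tsv(config.taxonomy)
        genome_ids = sorted(set(taxonomy.genome_ids) | {r.genome_id for r in focal})
        summary = bgc_io.summarize_collection(focal, taxonomy, genome_ids)
        summary_report = summary.as_dict()
        _write_json(summary_report, out / "collection_summary.json")

    report = {
        "n_bgcs": len(focal),
        "n_gcfs": len(gcfs),
        "n_gcfs_with_focal_member": len(gcfs),
        "novelty": novelty_summary,
        "venn_total": venn.total,
        "collection_summary": summary_report,
        "config": config.echo(),
    }
    _write_json(report, out / "genomic_report.json")
    return report


def run_metabolomic(config: RunConfig) -> dict:
    """Spectra -> molecular network -> blank curation -> census + mass checks."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not config.spectra:
        raise ValueError("config key 'spectra' is unset: path to a sample MGF")
    if not Path(config.spectra).exists():
        raise FileNotFoundError(f"config spectra: no such file {config.spectra}")
    spectra = specnet.read_mgf(config.spectra)
    if config.blanks:
        if not Path(config.blanks).exists():
            raise FileNotFoundError(f"config blanks: no such file {config.blanks}")
        for s in specnet.read_mgf(config.blanks):
            s.source = "blank"
            spectra.append(s)
    params = config.network_params()
    prepped = specnet.preprocess_all(spectra)
    net = specnet.build_network(prepped, params, preprocessed=True)
    census_raw = specnet.family_census(net)
    curated = specnet.remove_blank_components(net, prepped, preprocessed=True)
    census = specnet.family_census(curated)
    specnet.write_edge_tsv(curated, out / "network_edges.tsv")
    specnet.write_graphml(curated, out / "network.graphml")
    log.info(
        "network: %d nodes, %d singletons, %d families after blank curation",
        census.n_nodes, census.n_singletons, census.n_families,
    )

    mass_rows = []
    compounds = masscalc.load_reference_compounds()
    for check in config.mass_checks:
        formula = (
            compounds[check["compound"]]
            if "compound" in check
            else masscalc.parse_formula(check["formula"])
        )
        assignments = [(a["adduct"], float(a["observed_mz"])) for a in check["ions"]]
        mass_rows.extend(masscalc.mass_check(formula, assignments))
    if mass_rows:
        lines = ["formula\tadduct\ttheoretical_mz\tobserved_mz\tppm_error"]
        for r in mass_rows:
            lines.append(
                f"{r['formula']}\t{r['adduct']}\t{r['theoretical_mz']:.5f}"
                f"\t{r['observed_mz']:.5f}\t{r['ppm_error']:.2f}"
            )
        (out / "mass_check.tsv").write_text("\n".join(lines) + "\n")

    report = {
        "census_raw": census_raw.as_dict(),
        "census_curated": census.as_dict(),
        "n_mass_checks": len(mass_rows),
        "max_abs_ppm": max((abs(r["ppm_error"]) for r in mass_rows), default=None),
        "config": config.echo(),
    }
    _write_json(report, out / "metabolomic_report.json")
    return report
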