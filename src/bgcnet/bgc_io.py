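"""Reading, writing and summarising biosynthetic gene cluster (BGC) records.

A BGC here is one antiSMASH-style ``region``: a genomic locus predicted to
encode the biosynthesis of a secondary metabolite, annotated with the PFAM
domains found inside it.  Records enter the pipeline either from antiSMASH
region GenBank files or from a plain domain-table TSV exchange format, and
every record is binned into one of six product categories (RiPP, NRP,
Polyketide, Terpene, Hybrids, Others).
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

CATEGORIES = ("RiPP", "NRP", "Polyketide", "Terpene", "Hybrids", "Others")

#: Fixed column order of the domain-table TSV exchange format.
DOMAIN_TABLE_COLUMNS = (
    "bgc_id",
    "genome_id",
    "collection",
    "contig_id",
    "start",
    "end",
    "products",
    "contig_edge",
    "domains",
)


@dataclass(frozen=True)
class DomainHit:
    """One PFAM-style domain annotation inside a BGC."""

    domain_id: str
    bitscore: float = 1.0

    def __post_init__(self) -> None:
        if not self.domain_id:
            raise ValueError("domain_id must be nonempty")
        if self.bitscore < 0:
            raise ValueError(f"bitscore must be >= 0, got {self.bitscore}")


@dataclass
class BGCRecord:
    """One predicted biosynthetic gene cluster.

    Coordinates are 0-based half-open on ``contig_id``; GenBank 1-based
    inclusive positions are converted on read.
    """

    bgc_id: str
    genome_id: str
    collection: str
    contig_id: str
    start: int
    end: int
    product_types: list[str]
    on_contig_edge: bool
    domains: list[DomainHit] = field(default_factory=list)
    category: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"{self.bgc_id}: need 0 <= start < end, got [{self.start}, {self.end})"
            )
        if not self.category:
            self.category = map_category(self.product_types)
        if self.category not in CATEGORIES:
            raise ValueError(f"{self.bgc_id}: unknown category {self.category!r}")


@dataclass
class CollectionSummary:
    n_bgcs: int
    n_genomes: int
    bgcs_per_genome_mean: float
    bgcs_per_genome_median: float
    contig_edge_fraction: float
    category_fractions: dict[str, float]
    per_genus_density: dict[str, float]

    def as_dict(self) -> dict:
        return {
            "n_bgcs": self.n_bgcs,
            "n_genomes": self.n_genomes,
            "bgcs_per_genome_mean": self.bgcs_per_genome_mean,
            "bgcs_per_genome_median": self.bgcs_per_genome_median,
            "contig_edge_fraction": self.contig_edge_fraction,
            "category_fractions": dict(self.category_fractions),
            "per_genus_density": dict(self.per_genus_density),
        }


class TaxonomyTable:
    """genome_id -> (phylum, class, genus, species) lookup, TSV-backed."""

    COLUMNS = ("genome_id", "phylum", "class", "genus", "species")

    def __init__(self, frame: pd.DataFrame):
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"taxonomy table missing columns: {sorted(missing)}")
        if frame["genome_id"].duplicated().any():
            dupes = frame.loc[frame["genome_id"].duplicated(), "genome_id"].tolist()
            raise ValueError(f"duplicate genome_id in taxonomy: {dupes[:5]}")
        self._frame = frame.set_index("genome_id", drop=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "TaxonomyTable":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def write_tsv(self, path: str | Path) -> None:
        self._frame.to_csv(path, sep="\t", index=False, columns=list(self.COLUMNS))

    def genus_of(self, genome_id: str) -> str | None:
        if genome_id in self._frame.index:
            return self._frame.at[genome_id, "genus"]
        return None

    @property
    def genome_ids(self) -> list[str]:
        return self._frame["genome_id"].tolist()

    def __len__(self) -> int:
        return len(self._frame)


def _load_category_map() -> dict[str, str]:
    text = resources.files("bgcnet.data").joinpath("product_categories.yaml").read_text()
    table = yaml.safe_load(text)
    out: dict[str, str] = {}
    for base, products in table.items():
        for p in products:
            out[str(p).lower()] = base
    return out


_CATEGORY_MAP: dict[str, str] | None = None


def product_base_class(product: str) -> str:
    """Map one raw antiSMASH product string to its base class (or Others)."""
    global _CATEGORY_MAP
    if _CATEGORY_MAP is None:
        _CATEGORY_MAP = _load_category_map()
    return _CATEGORY_MAP.get(product.strip().lower(), "Others")


def map_category(product_types: Sequence[str]) -> str:
    """Six-way category call for a BGC from its raw product strings.

    Distinct base classes (ignoring Others) >= 2 -> Hybrids; exactly one ->
    that class; none (empty or all-unknown products) -> Others.
    """
    bases = {product_base_class(p) for p in product_types} - {"Others"}
    if len(bases) >= 2:
        return "Hybrids"
    if len(bases) == 1:
        return next(iter(bases))
    return "Others"


# ---------------------------------------------------------------------------
# antiSMASH-style region GenBank I/O


def _domain_accession(qualifiers: Mapping[str, list[str]]) -> str | None:
    for xref in qualifiers.get("db_xref", []):
        acc = xref.split(":")[-1]
        if acc.startswith("PF"):
            return acc.split(".")[0]
    for key in ("identifier", "database"):
        vals = qualifiers.get(key, [])
        if vals:
            return vals[0].split(".")[0]
    return None


def parse_region_genbank(
    path: str | Path,
    genome_id: str | None = None,
    collection: str = "default",
) -> list[BGCRecord]:
    """Parse antiSMASH region GenBank into BGC records.

    One record per ``region`` feature; PFAM_domain features falling inside a
    region supply its domain hits (bitscore from the ``score`` qualifier,
    defaulting to 1.0).  ``contig_edge`` region qualifiers of "True"/"False"
    set the completeness flag.
    """
    path = Path(path)
    records: list[BGCRecord] = []
    try:
        seqrecords = list(SeqIO.parse(str(path), "genbank"))
    except ValueError as exc:
        raise ValueError(f"malformed GenBank {path}: {exc}") from exc
    for rec in seqrecords:
        gid = genome_id or rec.annotations.get("source", rec.id)
        regions = [f for f in rec.features if f.type == "region"]
        pfams = [f for f in rec.features if f.type == "PFAM_domain"]
        for i, region in enumerate(regions, start=1):
            r_start, r_end = int(region.location.start), int(region.location.end)
            quals = region.qualifiers
            number = quals.get("region_number", [str(i)])[0]
            products = [str(p) for p in quals.get("product", [])]
            edge = quals.get("contig_edge", ["False"])[0].strip().lower() == "true"
            domains = []
            for pf in pfams:
                p_start = int(pf.location.start)
                if not (r_start <= p_start < r_end):
                    continue
                acc = _domain_accession(pf.qualifiers)
                if acc is None:
                    continue
                score = float(pf.qualifiers.get("score", ["1.0"])[0])
                domains.append(DomainHit(acc, score))
            records.append(
                BGCRecord(
                    bgc_id=f"{rec.id}.region{int(number):03d}",
                    genome_id=gid,
                    collection=collection,
                    contig_id=rec.id,
                    start=r_start,
                    end=r_end,
                    product_types=products,
                    on_contig_edge=edge,
                    domains=domains,
                )
            )
    if not records:
        raise ValueError(f"{path}: no `region` feature found")
    return records


def write_region_genbank(records: Sequence[BGCRecord], path: str | Path) -> None:
    """Write records as a minimal antiSMASH-flavoured region GenBank.

    Each record becomes its own contig entry carrying one ``region`` feature
    and one ``PFAM_domain`` feature per domain hit (domains are laid out
    consecutively inside the region).  Sequence content is a placeholder.
    """
    seqrecords = []
    for rec in records:
        length = rec.end
        sr = SeqRecord(
            Seq("N" * length),
            id=rec.contig_id,
            name=rec.contig_id[:16],
            description=f"synthetic region record for {rec.bgc_id}",
            annotations={"molecule_type": "DNA", "source": rec.genome_id},
        )
        sr.features.append(
            SeqFeature(
                SimpleLocation(rec.start, rec.end),
                type="region",
                qualifiers={
                    "region_number": ["1"],
                    "product": list(rec.product_types),
                    "contig_edge": ["True" if rec.on_contig_edge else "False"],
                },
            )
        )
        span = max(1, (rec.end - rec.start) // max(1, len(rec.domains) + 1))
        for j, hit in enumerate(rec.domains):
            d_start = rec.start + j * span
            d_end = min(rec.end, d_start + max(1, span // 2))
            sr.features.append(
                SeqFeature(
                    SimpleLocation(d_start, d_end),
                    type="PFAM_domain",
                    qualifiers={
                        "db_xref": [f"{hit.domain_id}.1"],
                        "score": [f"{hit.bitscore:g}"],
                    },
                )
            )
        seqrecords.append(sr)
    SeqIO.write(seqrecords, str(path), "genbank")


# ---------------------------------------------------------------------------
# Domain-table TSV exchange format


def _format_domains(domains: Iterable[DomainHit]) -> str:
    toks = []
    for d in domains:
        if d.bitscore == 1.0:
            toks.append(d.domain_id)
        else:
            toks.append(f"{d.domain_id}:{d.bitscore:g}")
    return ";".join(toks)


def _parse_domains(cell: str) -> list[DomainHit]:
    if not cell or pd.isna(cell):
        return []
    hits = []
    for tok in str(cell).split(";"):
        tok = tok.strip()
        if not tok:
            continue
        if ":" in tok:
            acc, score = tok.split(":", 1)
            hits.append(DomainHit(acc, float(score)))
        else:
            hits.append(DomainHit(tok, 1.0))
    return hits


def parse_domain_table(path: str | Path) -> list[BGCRecord]:
    """Read the TSV exchange format (see :data:`DOMAIN_TABLE_COLUMNS`)."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(DOMAIN_TABLE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"domain table {path} missing columns: {sorted(missing)}")
    if frame["bgc_id"].duplicated().any():
        dupes = frame.loc[frame["bgc_id"].duplicated(), "bgc_id"].tolist()
        raise ValueError(f"duplicate bgc_id in {path}: {dupes[:5]}")
    records = []
    for row in frame.itertuples(index=False):
        try:
            start, end = int(row.start), int(row.end)
        except ValueError as exc:
            raise ValueError(
                f"{path}: non-integer coordinates for {row.bgc_id}: "
                f"start={row.start!r} end={row.end!r}"
            ) from exc
        products = [p for p in str(row.products).split(";") if p]
        records.append(
            BGCRecord(
                bgc_id=row.bgc_id,
                genome_id=row.genome_id,
                collection=row.collection,
                contig_id=row.contig_id,
                start=start,
                end=end,
                product_types=products,
                on_contig_edge=str(row.contig_edge).strip().lower() == "true",
                domains=_parse_domains(row.domains),
            )
        )
    return records


def write_domain_table(records: Sequence[BGCRecord], path: str | Path) -> None:
    rows = [
        {
            "bgc_id": r.bgc_id,
            "genome_id": r.genome_id,
            "collection": r.collection,
            "contig_id": r.contig_id,
            "start": r.start,
            "end": r.end,
            "products": ";".join(r.product_types),
            "contig_edge": "True" if r.on_contig_edge else "False",
            "domains": _format_domains(r.domains),
        }
        for r in records
    ]
    frame = pd.DataFrame(rows, columns=list(DOMAIN_TABLE_COLUMNS))
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Collection summaries


def summarize_collection(
    records: Sequence[BGCRecord],
    taxonomy: TaxonomyTable | None,
    genome_ids: Sequence[str],
) -> CollectionSummary:
    """Per-genome BGC statistics, contig-edge fraction and category mix.

    ``genome_ids`` is the full genome roster: genomes without a single BGC
    contribute a count of zero to the per-genome mean and median.
    """
    if not genome_ids:
        raise ValueError("genome_ids must be nonempty")
    roster = list(dict.fromkeys(genome_ids))
    unknown = {r.genome_id for r in records} - set(roster)
    if unknown:
        raise ValueError(f"records reference genomes outside roster: {sorted(unknown)[:5]}")
    counts = {g: 0 for g in roster}
    for r in records:
        counts[r.genome_id] += 1
    n_bgcs, n_genomes = len(records), len(roster)
    per_genome = list(counts.values())
    cat_counts = {c: 0 for c in CATEGORIES}
    n_edge = 0
    for r in records:
        cat_counts[r.category] += 1
        n_edge += bool(r.on_contig_edge)
    if n_bgcs:
        cat_fracs = {c: cat_counts[c] / n_bgcs for c in CATEGORIES}
        edge_frac = n_edge / n_bgcs
    else:
        cat_fracs = {c: 0.0 for c in CATEGORIES}
        edge_frac = 0.0
    density: dict[str, float] = {}
    if taxonomy is not None:
        genus_genomes: dict[str, list[str]] = {}
        for g in roster:
            genus = taxonomy.genus_of(g)
            if genus is not None:
                genus_genomes.setdefault(genus, []).append(g)
        for genus, genomes in sorted(genus_genomes.items()):
            density[genus] = sum(counts[g] for g in genomes) / len(genomes)
    return CollectionSummary(
        n_bgcs=n_bgcs,
        n_genomes=n_genomes,
        bgcs_per_genome_mean=n_bgcs / n_genomes,
        bgcs_per_genome_median=float(statistics.median(per_genome)),
        contig_edge_fraction=edge_frac,
        category_fractions=cat_fracs,
        per_genus_density=density,
    )
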