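"""Ground-truthed synthetic inputs for every pipeline stage.

Two generators emulate the shapes of real survey data without any wet-lab
or database dependency:

* BGC collections with planted gene-cluster-family structure: each family
  has a disjoint core set of domain accessions with family-level bitscores;
  members perturb the core by random domain drops (probability ``p_drop``)
  and random accessory additions (``p_add``).  With zero noise, members of
  a family are identical vectors (within-family cosine distance 0) and
  disjoint cores put distinct families at distance 1.

* MS/MS spectra of compound families: analogs share a family fragment set
  with family-level intensities; an analog's precursor offset shifts a
  random subset of its fragments (exercising the shift-tolerant match) and
  uniform low-intensity noise peaks are superimposed.  Designated blank
  families include one medium-blank spectrum so that blank-component
  removal has planted truth.

Every generator takes an explicit integer seed and is deterministic: the
same seed yields byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .bgc_io import BGCRecord, DomainHit, TaxonomyTable
from .specnet import Spectrum

#: Per-family product strings cycled over planted families, spanning the
#: six categories (the last entry is deliberately unmapped -> Others).
PRODUCT_CYCLE = (
    ["terpene"],
    ["NRPS"],
    ["T1PKS"],
    ["lanthipeptide-class-ii"],
    ["NRPS", "T1PKS"],
    ["hypothetical-metabolite"],
)

_PHYLA = ("Alphaproteobacteria", "Gammaproteobacteria", "Bacteroidota", "Firmicutes", "Actinobacteriota")


@dataclass
class GcfTruth:
    assignment: dict[str, int]
    family_cores: dict[int, list[str]]
    params: dict

    def to_json(self, path: str | Path) -> None:
        payload = {
            "assignment": self.assignment,
            "family_cores": {str(k): v for k, v in self.family_cores.items()},
            "params": self.params,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


@dataclass
class SpectraTruth:
    assignment: dict[str, int]
    blank_families: list[int]
    params: dict

    def to_json(self, path: str | Path) -> None:
        payload = {
            "assignment": self.assignment,
            "blank_families": self.blank_families,
            "params": self.params,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _domain_vocab(vocab_size: int) -> list[str]:
    return [f"PF{i:05d}" for i in range(1, vocab_size + 1)]


def gen_bgc_collection(
    n_families: int = 20,
    members_per_family: int = 5,
    vocab_size: int = 2000,
    core_size: int = 20,
    p_drop: float = 0.05,
    p_add: float = 0.05,
    collection_label: str = "biofilm",
    seed: int = 0,
    genomes_per_family: int = 2,
    edge_fraction: float = 0.08,
) -> tuple[list[BGCRecord], GcfTruth]:
    """Generate a BGC collection with planted GCF structure.

    Family cores are drawn disjoint, which requires
    ``vocab_size >= n_families * 2 * core_size`` (the factor 2 reserves an
    accessory pool of the same size for noise additions and for fresh
    reference families drawn later by :func:`gen_reference_overlap`).
    """
    if core_size < 5:
        raise ValueError("core_size must be >= 5")
    if vocab_size < n_families * 2 * core_size:
        raise ValueError(
            f"vocab_size {vocab_size} too small for {n_families} disjoint cores of "
            f"{core_size}; need >= {n_families * 2 * core_size}"
        )
    rng = np.random.default_rng(seed)
    vocab = _domain_vocab(vocab_size)
    order = rng.permutation(vocab_size)
    cores = {
        fam: sorted(vocab[i] for i in order[fam * core_size : (fam + 1) * core_size])
        for fam in range(n_families)
    }
    accessory = [vocab[i] for i in order[n_families * core_size :]]
    core_scores = {
        fam: {d: float(np.round(rng.uniform(20.0, 200.0), 2)) for d in cores[fam]}
        for fam in range(n_families)
    }
    records: list[BGCRecord] = []
    assignment: dict[str, int] = {}
    for fam in range(n_families):
        products = PRODUCT_CYCLE[fam % len(PRODUCT_CYCLE)]
        for m in range(members_per_family):
            kept = [d for d in cores[fam] if rng.random() >= p_drop]
            if not kept:
                kept = [cores[fam][int(rng.integers(core_size))]]
            hits = [DomainHit(d, core_scores[fam][d]) for d in kept]
            n_extra = int(rng.binomial(core_size, p_add))
            if n_extra:
                extras = rng.choice(len(accessory), size=n_extra, replace=False)
                hits += [
                    DomainHit(accessory[int(e)], float(np.round(rng.uniform(20.0, 200.0), 2)))
                    for e in sorted(extras)
                ]
            bgc_id = f"{collection_label}_f{fam:03d}_m{m:02d}"
            genome_id = f"{collection_label}_g{fam * genomes_per_family + (m % genomes_per_family):04d}"
            start = 1000 * m
            records.append(
                BGCRecord(
                    bgc_id=bgc_id,
                    genome_id=genome_id,
                    collection=collection_label,
                    contig_id=f"{genome_id}_c1",
                    start=start,
                    end=start + 900,
                    product_types=list(products),
                    on_contig_edge=bool(rng.random() < edge_fraction),
                    domains=hits,
                )
            )
            assignment[bgc_id] = fam
    truth = GcfTruth(
        assignment,
        cores,
        {
            "n_families": n_families,
            "members_per_family": members_per_family,
            "vocab_size": vocab_size,
            "core_size": core_size,
            "p_drop": p_drop,
            "p_add": p_add,
            "collection_label": collection_label,
            "seed": seed,
        },
    )
    return records, truth


def gen_reference_overlap(
    records: list[BGCRecord],
    truth: GcfTruth,
    fraction_shared: float = 0.4,
    p_perturb: float = 0.05,
    reference_label: str = "reference",
    seed: int = 1,
) -> tuple[list[BGCRecord], set[int]]:
    """Build a reference collection overlapping a planted focal collection.

    A ``fraction_shared`` of the focal families receive one perturbed copy
    in the reference (each core domain dropped with probability
    ``p_perturb``); the remaining reference families are drawn fresh from
    the accessory domain pool, disjoint from every focal core, so that
    unshared focal families sit at cosine distance 1 from the reference.
    """
    if not (0.0 <= fraction_shared <= 1.0):
        raise ValueError("fraction_shared must be in [0, 1]")
    rng = np.random.default_rng(seed)
    params = truth.params
    n_families = params["n_families"]
    core_size = params["core_size"]
    vocab = _domain_vocab(params["vocab_size"])
    used = {d for core in truth.family_cores.values() for d in core}
    free = sorted(set(vocab) - used)
    n_shared = int(round(fraction_shared * n_families))
    shared = set(int(f) for f in rng.choice(n_families, size=n_shared, replace=False))
    by_family: dict[int, list[BGCRecord]] = {}
    for r in records:
        by_family.setdefault(truth.assignment[r.bgc_id], []).append(r)
    out: list[BGCRecord] = []
    for fam in sorted(shared):
        template = by_family[fam][0]
        hits = [h for h in template.domains if rng.random() >= p_perturb]
        if not hits:
            hits = [template.domains[0]]
        out.append(
            BGCRecord(
                bgc_id=f"{reference_label}_shared_f{fam:03d}",
                genome_id=f"{reference_label}_g{fam:04d}",
                collection=reference_label,
                contig_id=f"{reference_label}_g{fam:04d}_c1",
                start=0,
                end=900,
                product_types=list(template.product_types),
                on_contig_edge=False,
                domains=hits,
            )
        )
    n_fresh = n_families - n_shared
    if n_fresh * core_size > len(free):
        raise ValueError("accessory pool too small for fresh reference families")
    pick = rng.permutation(len(free))
    for k in range(n_fresh):
        core = [free[int(i)] for i in pick[k * core_size : (k + 1) * core_size]]
        hits = [DomainHit(d, float(np.round(rng.uniform(20.0, 200.0), 2))) for d in sorted(core)]
        out.append(
            BGCRecord(
                bgc_id=f"{reference_label}_fresh_{k:03d}",
                genome_id=f"{reference_label}_gf{k:04d}",
                collection=reference_label,
                contig_id=f"{reference_label}_gf{k:04d}_c1",
                start=0,
                end=900,
                product_types=["hypothetical-metabolite"],
                on_contig_edge=False,
                domains=hits,
            )
        )
    return out, shared


def gen_spectra(
    n_families: int = 12,
    analogs_per_family: int = 4,
    n_fragments: int = 12,
    max_precursor_offset: float = 30.0,
    n_noise_peaks: int = 5,
    n_blank_families: int = 2,
    seed: int = 0,
    min_matched: int = 6,
) -> tuple[list[Spectrum], SpectraTruth]:
    """Generate spectra of compound families plus planted blank families.

    Families share ``n_fragments`` fragment peaks with family-level
    intensities; analog ``k`` carries a precursor offset that shifts a
    random half of its fragments, and ``n_noise_peaks`` faint uniform
    noise peaks are added per spectrum.  The first ``n_blank_families``
    families additionally emit one medium-blank spectrum identical to
    their first analog.
    """
    if n_fragments < min_matched:
        raise ValueError(f"n_fragments must be >= min_matched ({min_matched})")
    rng = np.random.default_rng(seed)
    spectra: list[Spectrum] = []
    assignment: dict[str, int] = {}
    blank_families = list(range(n_blank_families))
    for fam in range(n_families):
        # family fragment ladder, spaced >= 1 Da so 0.02 Da matching is unambiguous
        frags = np.sort(rng.uniform(100.0, 800.0, size=n_fragments * 3))
        keep = [frags[0]]
        for mz in frags[1:]:
            if mz - keep[-1] >= 1.0:
                keep.append(mz)
            if len(keep) == n_fragments:
                break
        if len(keep) < n_fragments:
            keep += list(900.0 + np.arange(n_fragments - len(keep)) * 2.0 + fam * 0.001)
        frag_mz = np.round(np.array(keep[:n_fragments]), 4)
        frag_int = np.round(rng.uniform(0.2, 1.0, size=n_fragments), 6)
        precursor = float(np.round(rng.uniform(850.0, 1000.0), 4))
        # one family-level mask of offset-tracking fragments, so every analog
        # pair matches fully (directly or via the precursor shift)
        family_mask = rng.random(n_fragments) < 0.5
        for k in range(analogs_per_family):
            offset = (
                0.0
                if k == 0 or max_precursor_offset <= 0
                else float(np.round(rng.uniform(0.0, max_precursor_offset), 4))
            )
            shifted = family_mask if offset else np.zeros(n_fragments, bool)
            mz = frag_mz + np.where(shifted, offset, 0.0)
            inten = frag_int.copy()
            if n_noise_peaks:
                noise_mz = np.round(rng.uniform(100.0, 1000.0, size=n_noise_peaks), 4)
                noise_int = np.round(rng.uniform(0.01, 0.05, size=n_noise_peaks), 6)
                mz = np.concatenate([mz, noise_mz])
                inten = np.concatenate([inten, noise_int])
            sid = f"fam{fam:03d}_a{k:02d}"
            spectra.append(
                Spectrum(
                    spectrum_id=sid,
                    precursor_mz=precursor + offset,
                    peaks=np.column_stack([mz, inten]),
                    charge=1,
                    source="sample",
                )
            )
            assignment[sid] = fam
        if fam in blank_families:
            sid = f"fam{fam:03d}_blank"
            spectra.append(
                Spectrum(
                    spectrum_id=sid,
                    precursor_mz=precursor,
                    peaks=np.column_stack([frag_mz, frag_int]),
                    charge=1,
                    source="blank",
                )
            )
            assignment[sid] = fam
    truth = SpectraTruth(
        assignment,
        blank_families,
        {
            "n_families": n_families,
            "analogs_per_family": analogs_per_family,
            "n_fragments": n_fragments,
            "max_precursor_offset": max_precursor_offset,
            "n_noise_peaks": n_noise_peaks,
            "n_blank_families": n_blank_families,
            "seed": seed,
        },
    )
    return spectra, truth


def gen_taxonomy(genome_ids: list[str], n_genera: int = 5, seed: int = 0) -> TaxonomyTable:
    """Deterministically assign genomes to genera for density summaries."""
    import pandas as pd

    if n_genera < 1:
        raise ValueError("n_genera must be >= 1")
    rng = np.random.default_rng(seed)
    genera = [f"Genus_{i:02d}" for i in range(n_genera)]
    rows = []
    for g in genome_ids:
        gi = int(rng.integers(n_genera))
        rows.append(
            {
                "genome_id": g,
                "phylum": _PHYLA[gi % len(_PHYLA)],
                "class": _PHYLA[gi % len(_PHYLA)],
                "genus": genera[gi],
                "species": f"{genera[gi]} sp. {g}",
            }
        )
    return TaxonomyTable(pd.DataFrame(rows, columns=list(TaxonomyTable.COLUMNS)))
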