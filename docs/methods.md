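# Methods

## BGC records and product categories

A BGC is one antiSMASH-style `region`: coordinates (stored 0-based
half-open; GenBank's 1-based inclusive positions are converted on read), a
contig-edge flag marking clusters truncated by the end of an assembly
contig, raw product strings, and PFAM-domain hits with bitscores (missing
bitscores default to 1.0, so binary featurisation is the degenerate case).
Products are mapped to six categories via a shipped, editable YAML table
(`data/product_categories.yaml`): each raw string resolves to a base class
(RiPP — including every lanthipeptide class — NRP, Polyketide, Terpene) or
falls to Others; a BGC whose products span ≥ 2 distinct base classes
(ignoring Others) is a Hybrid. The table ships the common antiSMASH 6
vocabulary; vocabulary drift is configuration, not code.

Collection summaries include genomes with zero BGCs in the per-genome mean
and median (omitting them would bias both statistics upward), report the
contig-edge fraction as an exact count ratio, and compute per-genus BGC
density (BGC count / genome count) only for genera present in the supplied
taxonomy table.

## Features and distances

Each BGC becomes a sparse nonnegative vector over the lexicographically
sorted union of domain accessions across all pooled collections (focal and
reference collections share one vocabulary). Three weighting modes exist —
binary, count, and bitscore-summed — with bitscore as the default: the
per-domain evidence weighting is the closest available analogue of
HMM-score-based cluster featurisation, and the downstream contract
(nonnegative sparse vectors, cosine geometry) is identical in all modes.
Whether binary or weighted features better separate real families is
data-dependent, which is why the mode is a config knob rather than fixed.

Cosine distance 1 − u·v/(‖u‖‖v‖) lies in [0, 1] for nonnegative vectors;
distances below 1e-12 are snapped to zero so proportional vectors are
exactly coincident. Cosine distance is not a metric (the triangle
inequality can fail), so the clustering treats it purely as a
dissimilarity; no metric-dependent shortcut is used. All arithmetic is
double precision; pairwise matrices are dense and O(n²) in memory, which
is the practical ceiling of roughly 10⁴ BGCs on a desktop machine.

## GCF clustering

Average-linkage (UPGMA) agglomerative clustering on the precomputed cosine
matrix, cut with a strict rule: merging proceeds while the smallest current
linkage distance is < the threshold (default 0.2), so two clusters whose
average distance is exactly 0.2 stay separate — consistent with the strict
"> 0.2" novelty call on the same scale. The merge tree comes from
`scipy.cluster.hierarchy.linkage`; the strict cut walks the tree with a
union-find. Average linkage is monotone, so the walked prefix equals the
strict-threshold cut. Labels are densely renumbered by first member
appearance; with continuous-valued distances, ties are measure-zero, and
the tie behaviour that remains (scipy's merge ordering) is deterministic
for a fixed matrix.

Each family's representative is its medoid — the member minimising summed
distance to the other members, ties broken by lexicographically smallest
BGC id — chosen because it is the member-level analogue of a consensus
cluster and requires no extra model. The GCF category is the majority
category of the members, ties broken by the fixed order Hybrids > RiPP >
NRP > Polyketide > Terpene > Others (rarer, more informative classes win
ties). The GCF–GCF distance is the minimum cosine distance over cross
pairs.

## Novelty (d⁻) and Venn specificity

d⁻ of a GCF against a reference collection is the mean over member BGCs of
each member's minimum cosine distance to any reference BGC
(`method="member-mean"`, the default). The alternative reading — the
single minimum distance between the family and the reference pool — is
exposed as `method="gcf-min"` for comparison; the default follows the
"mean minimum" construction. A family is novel iff d⁻ > threshold
(strict, default 0.2). Reported percentages are rounded half-up to one
decimal. Adding reference vectors can only lower a member's minimum, so
d⁻ is monotone non-increasing in the reference — a property test.

Venn specificity counts each GCF once under its exact set of source
collections; "common" families appear in every declared source and
"X-specific" families in exactly one.

## Molecular networking

Preprocessing keeps a peak only if it ranks within the top 6 by intensity
inside ±50 Da of its own m/z, replaces intensities by their square roots
(damping dominant base peaks; configurable off) and L2-normalises, so the
modified cosine of two spectra is the plain sum of matched intensity
products, in [0, 1], and self-similarity is exactly 1.

Modified cosine: candidate fragment pairs match within the fragment
tolerance (default 0.02 Da) either directly or after shifting by the
precursor mass difference; a one-to-one matching is chosen greedily by
descending intensity product (standard practice, and cheap). The exact
maximum-weight matching (via `scipy.optimize.linear_sum_assignment`) is
available as `method="optimal"` and is used in tests as the oracle; on
random 5–8-peak spectra the greedy score equals the optimum ≈ 99 % of the
time and never exceeds it. Greedy ties on intensity product break by peak
index, which in principle can break exact symmetry on tied products;
products of continuous intensities make this measure-zero, and symmetry is
property-tested.

Edges require cosine ≥ 0.70 and ≥ 6 matched peaks (defaults). Topology
follows the GNPS conventions: an edge survives only if both endpoints rank
each other within their top-K neighbours by cosine (K = 10 by default;
K ≤ 0 disables the filter), then any connected component exceeding the cap
(default 100 nodes) repeatedly loses its lowest-cosine edge — ties broken
by lexicographic node pair — until all components comply. Blank curation
is automated: every component containing a blank-derived node, or a sample
node matching some blank spectrum at the network thresholds with
precursors within the parent-mass tolerance, is removed wholesale. The
census (nodes / singletons / connected nodes / families of ≥ 2 nodes) is
computable both before and after the top-K filter and blank curation; the
pipeline reports the raw and curated censuses.

## Mass arithmetic

Monoisotopic masses come from a shipped element table (H, C, N, O, F, Na,
P, S, Cl, K, Br, I at ~7 decimals); carbon is exactly 12 by definition.
Cation masses are electron-corrected (proton 1.007276 Da, Na⁺ 22.989218
Da), giving the fixed identity [M+Na]⁺ − [M+H]⁺ = 21.981942 Da for every
formula. Dehydration fragments are [M+H−kH₂O]⁺ with H₂O = 18.010565 Da.
ppm errors are signed: 10⁶ × (observed − theoretical)/theoretical. Only
singly charged ions are supported. Alteramide A (C29H38N2O6, monoisotopic
510.27299 Da) ships as a named reference compound in
`data/reference_compounds.tsv` so tests and configs reference chemistry by
name rather than hardcoding formulas.

## Synthetic data: what it emulates, and what it does not

The BGC generator plants `n_families` disjoint core domain sets
(`core_size` ≥ 5, default 20, matching a typical multi-gene cluster's
domain count) with family-level bitscores; each member drops each core
domain with probability `p_drop` and gains binomially many accessory
domains with probability `p_add` per core slot (defaults 0.05, a
perturbation level at which planted structure is still recoverable but not
trivial). Disjointness requires `vocab_size ≥ 2 · n_families · core_size`
(default vocabulary 2000 accessions, the order of distinct PFAM domains in
a real multi-genus isolate collection). In the zero-noise limit,
within-family distances are exactly 0 and between-family distances exactly
1, so threshold recovery is forced — a geometry guarantee the tests
assert. The reference-overlap generator gives a chosen fraction of focal
families perturbed reference copies and draws the rest fresh from the
unused domain pool, so the expected novel fraction is 1 − fraction_shared.

The spectra generator plants compound families sharing `n_fragments`
(default 12) well-separated fragment peaks with family-level intensities;
analogs differ by a precursor offset that shifts a fixed family subset of
fragments (exercising the shift-tolerant match), plus faint uniform noise
peaks. Blank families additionally emit one medium-blank scan. Every
generator takes an explicit seed, uses one `numpy` Generator and no global
state, and writes byte-identical files on reruns with the same seed.

What the generators do not emulate: real PFAM domain co-occurrence and
shared-domain overlap between genuine families (real GCF boundaries are
much softer than planted disjoint cores), contig fragmentation of BGCs,
isotope envelopes, chimeric/co-eluting spectra, retention time, and
intensity noise on shared fragments. Passing the recovery tests therefore
demonstrates that the pipeline's machinery is correct and deterministic
under controlled geometry — not that a 0.2 cosine threshold is optimal for
any particular real data set.

## Problem sizes and numerical choices

Tests and the reproduction script run at desk scale, chosen to exercise
every code path while completing in seconds: 50 planted families × 3–5
members (≈ 150–250 BGCs, 2000-domain vocabulary) for clustering and
novelty recovery; 100 random instances of n ≤ 40 for the independent
agglomerator comparison; 500 random 5–8-peak pairs for the matcher
comparison; 12–20 compound families (≈ 50–82 spectra) for networking.
Distances are float64 throughout; cosine values are clipped to [0, 1];
equality comparisons in tests use absolute tolerances of 1e-9–1e-12.

## Known limitations

- O(n²) distance matrices and all-pairs spectral scoring bound practical
  input sizes (~10⁴ BGCs, ~10³ spectra per run).
- Domain-vector cosine ignores domain order and copy-number synteny;
  alignment-based BGC similarity is out of scope.
- The greedy peak matcher can under-score dense spectra with many
  near-ties; the exact matcher is available but quadratic-cubic in peaks.
- mzXML/vendor conversion, spectral library annotation and multi-charge
  ions are out of scope; spectra enter as centroided MGF.
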