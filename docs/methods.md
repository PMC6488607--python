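# Methods

## The problem

Mass-spectrometry phosphoproteomics yields very large catalogues of
phosphorylated serines, threonines and tyrosines, but only a small
minority of sites have any annotated function. One strong signal of
functional relevance is recurrence: if many different instances of the
same protein domain family — across paralogs and across species — are
phosphorylated at the same region of the domain, that region is a
candidate regulatory element of the whole family (the protein-kinase
activation loop is the canonical example). `phosfam` detects such
*phosphorylation hotspot regions* on domain-family multiple sequence
alignments and annotates them with functional and structural evidence.

## Statistical model

For one family, let the alignment have `L` columns and let `n(c)` be the
number of phosphosites observed at column `c`, summed over all aligned
instances. The per-column statistic is a centred rolling-window mean

    W(c) = ( Σ_{c' ∈ win(c)} n(c') ) / |win(c)| ,

with `win(c)` the columns within ±⌊w/2⌋ of `c` intersected with
`[1, L]`. The default width `w = 5` absorbs three sources of positional
blur: phosphosite localization error within the identified
phosphopeptide, evolutionary drift of the exact acceptor position, and
alignment uncertainty. Edge windows are truncated and averaged over
their actual width rather than zero-padded, so border columns are not
biased downward by phantom zeros.

The null model asks: what would `W` look like if the same number of
phosphosites had landed on *random* acceptor residues? Each permutation
redraws site positions uniformly without replacement among
phospho-acceptor residues (S/T/Y), preserving the total count of each
acceptor type. Two scopes are implemented:

* `per_sequence` (default): each row's S, T and Y site counts are
  reshuffled among that row's own S, T and Y positions. This preserves
  per-protein phosphorylation load and is the more conservative null.
* `per_alignment`: type-wise totals are reshuffled across all acceptor
  residues of the whole alignment.

Over `B` permutations (default 100) the per-column median `m(c)` and
population standard deviation `s(c)` of the permuted window profile are
collected, and the observed profile is scored as

    z(c) = (W(c) − m(c)) / s(c),   p(c) = Φ̄(z(c)),

with `Φ̄` the standard normal survival function. Only enrichment is
tested, never depletion. Degenerate columns with `s(c) = 0` get
`p = 1` when `W(c) ≤ m(c)` and the standard permutation lower bound
`1/(B+1)` when the observed value exceeds a null that can never move.

Multiple testing is controlled family-wise and *globally*: the Bonferroni
threshold is `α / n_tests` with `n_tests` the total number of columns
over all eligible families (by default including columns without
acceptors; a restriction flag exists). With `α = 0.01`, a corrected
cutoff of 0.01 pairs with an uncorrected threshold of 6.70 × 10⁻⁸ at
149,254 tests. A column is called significant only if it additionally
passes an effect-size floor of `W(c) ≥ 2` phosphosites per position,
which suppresses statistically significant but biologically negligible
excesses in very deep alignments.

Maximal runs of contiguous significant columns are extended by ±2
columns, clipped to the alignment, and extended intervals that overlap,
share an endpoint or are directly adjacent are merged into one region
(adjacent intervals cover a contiguous column range, so keeping them
separate would split one contiguous candidate region in two).

### Eligibility and site preprocessing

Families are tested only when supported by at least 10 phospho-bearing
domain instances carrying at least 50 mapped phosphosites (counted after
deduplication — sites are deduplicated before any mapping). Within each
species, sites sharing an identical 11-mer sequence context (site ±5
residues, termini padded with `-`) are collapsed to one representative
(first by sorted protein id, then position); species whose source
database already provides canonical-isoform, non-redundant sites can be
exempted from the peptide rule. Sites are validated against the
reference proteome: a site whose stated residue does not match the
sequence is dropped and counted, never remapped. A site inside
overlapping instances of different families counts for each family;
inside overlapping instances of the *same* family it counts once, on the
instance with the smallest envelope start.

## Validation statistics

* **ROC/AUC.** Sites are scored by `−log10` of their column's hotspot
  p-value; the AUC for discriminating regulatory from non-regulatory
  sites is the Mann–Whitney rank statistic with tie averaging, computed
  separately for S/T and Y.
* **Regulatory enrichment.** A one-sided (greater) Fisher's exact test
  on (inside/outside hotspot) × (regulatory/not), on a per-site
  universe restricted to families contributing more than one regulatory
  site of the tested class.
* **Structural feature enrichment.** One-sided Fisher tests of hotspot
  versus other residues of the same domains, for: accessibility
  (RSA > 20%), disorder, catalytic identity, catalytic proximity within
  5 aa (sequence) and within 5 Å / 15 Å (minimum heavy-atom distance;
  Cα mode available), and interface membership (contacts with another
  protein chain in ≥ 10 structures). The interface test restricts its
  universe to accessible residues so it is not confounded by exposure.
  All proximity thresholds are inclusive. The sample odds ratio
  `ad/bc` is reported, `+inf` when `bc = 0`, with the raw counts always
  emitted.

## Structural representative

Per family, candidate PDB chains are first filtered: any internal chain
break longer than one residue disqualifies a model, as does a length
below 70% of the longest candidate. Pairwise Cα RMSD is computed with a
native Kabsch superposition (least-squares proper rotation; reflections
excluded) over the alignment columns resolved in both models, followed
by single-linkage clustering at 3.5 Å (configurable). The "most common
conformation" is taken as the largest cluster, and its medoid — the
member minimizing mean RMSD to its cluster mates — is the
representative; ties go to the longer model, then the lexicographically
smaller identifier. Hotspot columns are carried onto the representative
through its alignment row; regions falling entirely in unresolved
segments are flagged as lacking structural coverage rather than
silently dropped.

## Synthetic data generator

The generator emulates the data shape the detector consumes, with exact
ground truth. Each family is built on a master alignment of
`domain_length` columns (default 120); each of `instances_per_family`
rows (default 30) deletes each column independently with probability
`indel_rate` (0.03), draws S/T/Y at kept columns with probabilities
0.083/0.055/0.029 (eukaryotic proteome frequencies) and other residues
uniformly otherwise, and phosphorylates each acceptor independently with
probability `baseline_rate` (default 0.15), multiplied by
`enrichment_factor` inside the designated hotspot columns (capped at 1;
the factor is multiplicative, so a zero baseline silences every column).
Domains are embedded between random non-acceptor flanks so protein and
envelope coordinates are exercised. Regulatory labels are drawn at 0.5
inside and 0.05 outside true hotspot columns. Toy structures lay the Cα
trace of the first row on an ideal α-helix (or a 3.8 Å straight line)
with one side-chain pseudo-atom per residue, so every distance is
recomputable by hand.

The default baseline rate is chosen so that an average default family
carries ≈ 87 sites, clearing the ≥ 50-site eligibility filter by about
four standard deviations: the detector is only ever applied to eligible
families, so simulated families — including null ones — must be
eligible to be representative. At substantially sparser data the
normal-tail approximation to the discrete permutation null becomes
anti-conservative (measured fraction of columns with nominal p < 0.05:
≈ 0.080 at ~46 sites/family, ≈ 0.067 at ~74, approaching 0.05 as counts
grow); at the default density the empirical fraction is ≈ 0.067–0.069
and no null family yields a globally corrected region call.

What the generator does **not** emulate: phylogenetic correlation
between rows (rows are i.i.d., real alignments are tree-structured),
kinase-motif sequence context around sites, conservation gradients
along the domain, heterogeneous per-species detection depth, and real
indel placement. Passing calibration and power checks on these
synthetics therefore demonstrates correctness of the statistical
machinery under the stated sampling assumptions, not performance on any
particular real phosphoproteome compilation.

## Problem sizes and numerical choices

The shipped whole-method checks use 200 null families (30 × 120,
B = 1000) for calibration, 100 enriched families (50 instances, a
5-column hotspot at 10× baseline, B = 100) for power, and exhaustive
placement enumeration (≤ 10 placements) against B = 10,000 sampling for
the permutation oracle; all complete in seconds on one CPU. Null sd uses
the population divisor `B`; the null centre is the *median* of the
permuted profiles. Permutation streams are drawn from one seeded
generator in sorted family order, and every output is bit-reproducible
for a fixed seed. Boundary accuracy of recovered hotspots is measured
against the ±2-extended injected run: the rolling window necessarily
spreads significance up to ⌊w/2⌋ columns beyond a true run, and region
boundaries add the mandated ±2 extension, so the extended run is the
correct target for a detector behaving exactly as specified.

## Known limitations

* The normal-tail p-value is an approximation to the discrete
  permutation distribution; at sparse per-family site counts it is
  anti-conservative (numbers above). Interpret borderline calls on
  shallow families with care, or raise `B` and use the permutation
  bound directly.
* Alignment quality is taken on faith: the aligner is upstream and
  misaligned instances blur or shift hotspots.
* Domain instances are treated as independent evidence; shared ancestry
  between close paralogs and species inflates effective counts.
* Interface and disorder annotations are consumed as precomputed tables;
  their provenance and thresholds are the caller's responsibility.
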