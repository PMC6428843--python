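# Methods

## Scope and data model

The package operates downstream of a glycopeptide database search: its inputs
are centroid peak lists (MGF/mzML), protein sequences (FASTA), PSM export
tables (TSV), a glycan composition database (TSV) and protein annotation
tables (GO cellular-component terms; domain spans). Glycans are handled
purely compositionally — a multiset over {HexNAc, Hex, Fuc, NeuAc, Phospho} —
because fragmentation of intact glycopeptides does not reliably determine
topology or linkage. Mannose-6-phosphate is written as a `Phospho(1)` count
(e.g. `HexNAc(2)Hex(7)Phospho(1)`).

Residue monoisotopic masses are HexNAc 203.079373, Hex 162.052824,
Fuc 146.057909, NeuAc 291.095417, Phospho 79.966331 Da, with proton 1.007276
and water 18.010565 Da; these reproduce the standard printed oxonium values
(HexNAc 204.0867, Hex 163.06, NeuAc 292.1027, NeuAc−H₂O 274.0921,
HexNAc+Hex+NeuAc 657.2349) within 1 ppm. Amino-acid residue masses come from
pyteomics' standard table; carbamidomethyl-Cys (+57.021464) is the default
fixed modification.

## Glycan classes

Six categories are used: paucimannose, high mannose, complex/hybrid,
fucosylated, sialylated, M6P. The exclusive assignment follows the precedence
M6P → sialylated → fucosylated → high mannose → paucimannose → complex/hybrid,
so any NeuAc-bearing glycan is sialylated even when fucosylated. Because the
boundaries between mannose classes are conventions rather than chemistry, they
live in `ClassificationConfig`: high mannose = HexNAc exactly 2 with Hex ≥ 5
and nothing else; paucimannose = HexNAc exactly 2, Hex ≤ 4, at most one (core)
fucose; a fucosylated paucimannose core is classed fucosylated. Independent
multi-label flags (sialylated/fucosylated/M6P/high-mannose) are computed
alongside, and type-composition statistics use the multi-label rule in which
any fucose-bearing glycan also counts as fucosylated.

## Fragment calculus

Backbone ions b/y/c/z are generated per cleavable bond (1..L−1) and charge;
c = N-terminal residues + NH₃, z is generated as the z• radical
(C-terminal residues + H₂O − NH₂), matching the dominant electron-transfer
products. Fragments containing the glycosite are emitted in up to three glycan
retention modes: `intact` (full glycan mass added), `stub` (one HexNAc,
+203.079373) and `none` (bare backbone, the "~" ions of annotated spectra);
partial-glycan retention between stub and intact is deliberately not generated,
matching the five-class explained-ion-current accounting. The Y ladder
enumerates sub-compositions of the glycan on the composition lattice with the
constraint that a nonempty retained composition keeps ≥ 1 HexNAc (the
reducing-end core residue is lost last); the full composition (= precursor) is
excluded and Y0 is the bare peptide. This constraint is switchable for
non-standard core chemistry. Oxonium/B ions come from a configurable catalog
(name, composition, water losses). Fragments above a configurable m/z ceiling
(default 2000 Th, a typical MS/MS scan upper bound) are generated but flagged
out-of-range.

## Annotation metrics

Each theoretical ion is matched to the nearest observed peak within a ppm
tolerance (default 20 ppm for fragments, 10 ppm precursor); peaks below the
scan floor (default 115 Th) never match. When one peak matches several ions it
is classified once, by the priority plain backbone > backbone+glycan >
backbone+stub > Y > oxonium — double-matches are not defined away by physics,
and this ordering prevents double-counting of ion current while favoring the
information-richer assignment. Backbone coverage counts bonds evidenced by any
matched backbone ion over L−1; glycan coverage counts distinct matched Y
depths (including Y0) over the glycan residue count. Explained-ion-current
fractions are over matched intensity (they sum to 1 when anything matched),
with the matched/total ratio reported separately.

Diagnostic ratios are summed-intensity ratios over caller-supplied ion sets.
The GlcNAc/GalNAc decision thresholds are <1 → GalNAc, >2 → GlcNAc, otherwise
ambiguous; the shipped numerator/denominator m/z sets (126.055+138.055 /
144.0655+168.0655) are configuration, since the fragment sets are defined in
the oxonium-ratio literature rather than fixed by this package. The
sialylation flag is strict: ratio(274.0921/204.0867) > 0.1. The Ln/Nn linkage
ratio is exposed as a plain `intensity_ratio` call with caller-supplied sets
and no shipped default.

## Filtering cascade

Decoys are identified by an explicit boolean column (an accession-prefix
fallback, `rev_`, is exercised by the generator). The q-value at score
threshold t is the running minimum over decreasing score of
FDR(t) = #decoys ≥ t / #targets ≥ t, with tied scores sharing a value; the
plain decoys/targets estimator (not (d+1)/t) is used so that, e.g., one decoy
against 300 targets reads 0.33%. Steps run in the fixed order q ≤ 0.01,
score ≥ 150, length ≥ 5, |logProb| > 1, ≤ 1 glycosite, DeltaMod ≥ 10, then an
optional sequon check (on by default, as a guard for synthetic or third-party
inputs; search engines typically enforce it already). All predicates after the
q-value step are record-local, so the survivor set is order-invariant; the
per-step accounting telescopes and is what the report exposes. When the
dedicated ranking score column is absent the search score is used with a
warning. The glyco FDR counts only glycopeptide rows among survivors and is
undefined (None) without target glyco PSMs. The focused-database builder keeps
proteins evidenced by at least one peptide with a deamidated N inside a valid
N-X-S/T sequon, using protein context for sequons spanning the peptide
C-terminus.

## Heterogeneity analytics

The glycosite table holds unique (protein, 1-based protein site, glycan) rows
with PSM tallies; unique glycopeptide = (peptide sequence, glycan), matching
the granularity of typical reported counts. Co-occurrence cell (a, b) counts
sites where both glycans appear; the upper-triangle total equals
Σ_sites C(k, 2). Networks are exported as edge lists and GraphML in three
modes (bipartite glycan–protein, weighted co-occurrence, single-source star).

GO CC terms collapse to twelve groups by an ordered rule list (exact "plasma
membrane"; any other "membrane" → other_membrane; axon/neuro/myelin → neural;
Golgi-without-endoplasmic → Golgi; endoplasmic → ER; surface → cell_surface;
synap/vesicle/lysosom/secret-or-extracellular rules; unmatched →
other_cellular_component; no terms → none_listed). Proteins may belong to
several groups, so group profile totals can exceed the observation count —
deliberately, to mirror multi-term annotations; proteins without terms are
kept under none_listed so nothing is silently dropped. Profiles count unique
site–glycan pairs by default (PSM weighting is a switch, since "occurrences"
is ambiguous in the field); distances are plain Euclidean over the
glycan-indexed vectors.

Domain labels are collapsed to their broadest common term by stripping subtype
qualifiers (`C2-type`, `V-type`, trailing repeat numbers), e.g. all Ig-like
subtypes merge. A site maps to a domain instance when start ≤ site ≤ end
(1-based closed spans). The heterogeneity ratio is glycan-type–glycosite
combinations / glycosites — a site carrying three types counts three — over
the six types with the multi-label fucose rule. Composition differences are
mean-normalized: the domain's percentage per type minus the overall
percentage, so each domain's six differences sum to zero. Domains with fewer
than 7 glycosites (configurable) pool into "other domains". Domain ordering
uses agglomerative hierarchical clustering (Euclidean, average linkage by
default — the linkage choice is a convention, exposed as a parameter) over the
six-dimensional difference vectors, with label-lexicographic pre-sorting for
deterministic tie-breaks.

## Synthetic data generator

All randomness flows from one `numpy.random.default_rng(seed)` stream in a
documented draw order (proteome → assignments → PSMs → spectra), so equal
seeds give byte-identical outputs. The generator emulates:

- a glycoproteome (default 50 proteins of 250–500 residues) with planted
  N-X-S/T sequons at 0.01 per residue, 1–3 domain instances per protein from a
  catalog of common extracellular domain types, and 1–4 GO CC terms per
  protein;
- site–glycan assignments: each candidate site is occupied with probability
  0.85 and draws k glycans from a truncated geometric with continuation 0.6 —
  i.e. ~60% of occupied sites carry more than one glycan, the regime reported
  for brain tissue;
- a PSM table with 1 + Poisson(3.3) PSMs per site–glycan pair (≈ 4.3 PSMs per
  unique glycopeptide, as in large-scale studies), decoys at 10% of target
  rows, optional false targets, and optional planted violators of each
  cascade step. The ranking score separates correct rows (Normal(4,1),
  truncated ≥ 2.5) from decoys/false targets (Normal(0,1), truncated ≤ 2.0);
  the other quality scores are target-like and truncated to the passing side
  of every threshold for all rows, so removals beyond the q-value step are
  attributable solely to planted violators. This is the generator's contract:
  with no violators and generous thresholds, survivors equal emitted targets;
- MS/MS spectra: each theoretical fragment inside the scan window survives
  with detection probability p (default 0.7), m/z jittered with Gaussian ppm
  noise (default σ = 5 ppm, well inside the 20-ppm matching tolerance),
  class-wise log-normal intensities (arbitrary units — only ratios matter
  downstream), plus uniform noise peaks.

What the generator does **not** emulate: isotope envelopes and charge-state
interference, retention time, co-isolation/chimeric spectra, intensity
response differences between instruments, realistic decoy sequence
composition, and glycan fragmentation stacked on backbone fragments. Passing
recovery tests therefore demonstrates correctness of the bookkeeping and the
statistical calibration of the estimators under the stated model, not
instrument-grade identification performance on real data.

## Numerical choices and degenerate inputs

ppm matching uses a bisection window with nearest-in-ppm tie-break; annotation
of an empty spectrum returns all-zero metrics rather than an error. q-value
computation with no targets raises; with no decoys it returns all-zero
q-values with a warning. Glyco FDR with zero surviving target glyco PSMs is
None. An empty glycan forbids a Y ladder; a single-domain clustering returns
the identity ordering. Writers are temp-then-rename, TSV with fixed column
order and sorted rows, m/z to 4 decimals.

## Problem sizes used in the checks

The shipped test-suite and acceptance checks run at desk scale: ~1,000-row PSM
tables for cascade exactness, 100 simulated tables for FDR calibration, 500
spectra for coverage recovery, 200 random tables for the analytics
identities, and a 10–25-protein simulated study for end-to-end determinism.
Headline dataset sizes of a real experiment (thousands of glycosites) are not
re-derivable from synthetic data and are not targets of the checks.

## Known limitations

- Compositional glycan model only; no branching/linkage, no glycan topology
  scoring.
- The search engine's own scoring (including its ranking score) is consumed,
  never re-derived; protein-level FDR is assumed handled upstream.
- Internal fragments and glycan losses on backbone fragments are not
  generated.
- The GlcNAc/GalNAc and Ln/Nn diagnostic ion sets are configuration; the
  shipped GlcNAc/GalNAc defaults should be reviewed against the user's
  instrument and collision regime.
- The packaged 117-composition glycan database is a synthetic, size-matched
  fixture, not a curated biological list.
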