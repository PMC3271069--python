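# Methods

This note records the models, conventions and design choices behind the
four computational cores, what the synthetic generators do and do not
emulate, and the numerical details a maintainer would need.

## Spectral binning

A bin specification is a ppm region `[low, high]` divided into `n`
equal-width intervals. Intervals are half-open `[low, high)` with the
interval containing the region's upper boundary closed, so every grid
point in the region is counted exactly once and points outside are
ignored. Aggregation is **sum** by default: the sum of all bins then
equals the total in-region intensity exactly (machine precision), a
conservation law the tests enforce; `mode="mean"` is offered for users
who want resolution-independent bin heights. Bins are ordered downfield
→ upfield (high ppm first), matching the convention of the tab-delimited
bin-table format, whose header carries the bin-center labels — `8.900`
for 1D, `C125.000_H6.500` for 2D, encoding both plane coordinates of a
bin. 2D binning is the rectangular product of two 1D specifications,
flattened row-major with the ¹³C (F1) axis outer. Negative intensities
(legitimate in phased 2D spectra) pass through binning untouched.

The region-fraction summary clips negatives to zero before forming
fractions, because a pie chart is a distribution and a signed spectrum
is not. Defaults are 20 regions over −1…9 ppm (0.5 ppm each); each
region carries a palette position in [0, 1] mapping red = upfield (−1
ppm) to green = downfield (9 ppm). A spectrum with no positive in-region
intensity yields all-zero fractions and an `empty` flag rather than an
exception, so batch pipelines keep running.

## HSQC peak assignment

Matching is a per-axis box test: peak p matches entry e iff
|δ_H(p) − δ_H(e)| ≤ tol_H and |δ_C(p) − δ_C(e)| ≤ tol_C, with closed
intervals. Defaults tol_H = 0.03 ppm, tol_C = 0.53 ppm reflect the
roughly 18-fold larger dispersion (in ppm) of ¹³C shifts. When several
entries qualify, the winner minimizes the tolerance-normalized Euclidean
distance √((Δδ_H/tol_H)² + (Δδ_C/tol_C)²); normalizing by the tolerances
makes the two axes commensurate despite their different scales. Exact
ties resolve to the lexicographically smallest entry id, making results
order-independent. Each peak gets at most one assignment; many peaks may
share one entry (compositions report per-category hit counts, which this
supports). Unmatched peaks accumulate in an explicit `Others` bucket, so
matched + Others always partitions the peak list.

Composition modes: `intensity` sums matched peak intensities per
detailed category; `roi_assignment` counts matched peaks; `auto` uses
intensity exactly when every peak carries one. Requesting intensity mode
on an intensity-free list is an error pointing at the alternatives.

The packaged reference table is **synthetic**: the curated lignocellulose
database's individual chemical shifts are not published, so the package
ships a stand-in that reproduces its class structure (42 lignin-aromatic,
17 lignin-aliphatic, 26 hemicellulose, 3 uncategorized entries, 88 in
all) and category vocabulary, with centers drawn once (fixed seed) from
class-typical HSQC regions — aromatics ≈ 6–8 / 100–135 ppm, aliphatics
≈ 3–6 / 50–90 ppm, sugars ≈ 3–5.5 / 60–110 ppm — under a minimum
pairwise separation of 3 tolerance-normalized units. That separation
guarantees peaks jittered by less than half a tolerance per axis resolve
to their generating entry, which the recovery tests rely on. Conclusions
about real plant samples require a literature-derived table in the same
six-column TSV.

The category vocabulary includes an `Uncategorized` label, valid only
with the `uncategorized` signal class, to carry the database's few
signals outside the named lignin/hemicellulose chemistry.

## Correlation maps and significance

Inputs are row-ID × sample matrices; 1–4 of them (the cap mirrors the
original four-omics design and is configurable) are stacked row-wise
after checking a single shared column count. Columns are aligned by
position — the equal-column rule implies sample order is meaningful —
with an optional strict-label flag. Element (i, j) of the map is the
chosen coefficient between stacked rows i and j: Pearson's
product-moment r, Spearman's r (Pearson on average ranks, the standard
tie treatment), or cosine similarity. Zero-variance rows (Pearson/
Spearman) and zero-norm rows (cosine) make the coefficient undefined;
the map carries NaN there, top-pair extraction and the r histogram skip
them, and the heatmap renders them grey. The matrix is computed by one
normalized matrix product per method, symmetrized, clipped to [−1, 1],
and the diagonal of defined rows set to 1.

Significance uses the exact null distribution of the Pearson
coefficient: t = r√((n−2)/(1−r²)) ~ t(n−2), inverted to
r\* = t\*/√(n−2+t\*²). At n = 7 and α = 0.05 (two-sided) this gives
r\* = 0.7545 ≈ 0.75, the working cutoff for seven-sample time series. A
Monte-Carlo test confirms the 5% null exceedance to ±0.005. No
multiple-testing correction is applied by default (pair extraction is
exploratory screening); `critical_r(..., n_tests=k)` applies Bonferroni
for users who want it. The same |r| cutoff is applied verbatim to
Spearman and cosine maps, where it is a heuristic rather than an exact
test. Cutoff comparisons are strict (|r| > cutoff).

`top_pairs` returns unique unordered pairs with defined |r| strictly
above the cutoff, sorted by |r| descending with deterministic label
tie-breaks. `r_distribution` histograms the defined upper-triangle
values over equal-width bins spanning [−1, 1] (last bin closed).

## Hit classification and modularization

Hits above the E-value threshold (strictly greater) are dropped; the
best hit per query is the lowest E-value, ties broken by highest bit
score then lexicographic subject id — the tie rules are a package
choice, made explicit so results are reproducible. The query inherits
its subject's lineage truncated at the requested rank (`unclassified`
when the rank is missing or the subject lacks metadata, with a warning)
or the subject's CBM families for rank `CBM`. A multi-domain CBM subject
contributes one count per distinct family, so CBM counts can exceed the
number of unique queries; taxonomic fractions, computed over total
queries including `unassigned`, sum to 1. A FASTA-derived query roster
may be supplied so queries with zero passing hits are reported rather
than silently absent.

Modularization: the edge criterion for the similarity graph is an
E-value threshold on an all-vs-all hit table (an undirected edge when
either direction passes; self-hits ignored) — the criterion is a
parameter because no single choice suits every marker gene. Modules are
connected components, singletons included; the representative is the
member with maximum within-module degree ("connected to the most module
members"), ties to the smallest id. The representative list is the
reduced database; the reduction ratio |modules|/|nodes| quantifies the
speedup. Component detection is order-invariant and is cross-checked
against a flood-fill oracle.

## Synthetic data

The generators model the study shapes, not the instruments:

- `gen_spectrum` sums Gaussian lines (amplitude · exp(−Δ²/2w²)) on a
  regular ppm grid plus i.i.d. Gaussian noise. Real NMR lines are
  Lorentzian-tailed, J-coupled and phase-imperfect; none of that is
  emulated, so passing binning tests demonstrate correct digitization,
  not robustness to instrumental artefacts.
- `gen_correlated_matrices` plants row pairs sharing one standard-normal
  latent factor (sign-flipped for negative associations) plus
  independent N(0, σ²) noise, defaults n = 7 samples and σ = 0.05 —
  a small-n time series with strong planted associations. Real omics
  rows are compositional, autocorrelated and heteroscedastic; the
  parameter-recovery results (≥ 99% detection, 5% null rate) are
  statements about this idealization.
- `gen_hit_table` plants one best hit per query inside the requested
  E-value range and adds decoys at E-values at least 10³× worse, so the
  intended label always wins under the tie rules.
- `gen_similarity_graph` builds disjoint modules with an optional hub
  wired to all members (the hub is the unique degree maximum for sizes
  ≥ 3).

Every generator takes a seed and owns a private `numpy` Generator; equal
configurations produce byte-identical serialized output.

## File formats and numerics

Tab-delimited matrices: first column row IDs, optional first-row header
auto-detected (a fully numeric non-ID first row is data; pass
`has_header` explicitly for bin tables, whose labels are numeric).
Duplicate row IDs are an error because downstream maps key rows by ID.
Decimal points only; UTF-8; `\n` or `\r\n`; empty cells rejected
(correlations assume complete vectors). Writers emit 17 significant
digits, so read(write(x)) is exact for doubles.

Spectra: a documented `plain-grid` text dialect (1D: `ppm<TAB>intensity`
per line; 2D: first row the F2 ppm axis, first column the F1 axis) is
the primary format; a minimal single-file nmrPipe binary reader/writer
(512 float32 header words, little- or big-endian, ppm axis reconstructed
from OBS/SW/ORIG per axis) covers pipeline output. Axes are stored
strictly monotone descending; ascending input is flipped on read.
nmrPipe storage is float32, so round-trips are exact only to single
precision.

Problem sizes throughout the tests and the acceptance script (spectra of
a few hundred points, maps of tens of rows, 10³–10⁵ Monte-Carlo
replicates) were chosen to exercise every code path while keeping the
full suite around two seconds.

## Known limitations

- No phasing, baseline correction, solvent exclusion or normalization:
  spectra are assumed processed.
- No peak picking: the HSQC assigner consumes a peak list.
- The alignment step itself is external; only its tabular output is
  consumed, and no real 16S/18S/SSU/CBM reference databases ship with
  the package.
- Matching resolves each peak to a single entry; overlapping ROIs that
  genuinely share a peak are winner-takes-all.
- The correlation map is dense; for very large bin matrices (> a few
  thousand rows) memory grows quadratically.
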