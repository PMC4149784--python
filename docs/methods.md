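# Methods

`regulonprint` implements the desk-scale computational analysis of a
chemical-biology experiment in which a copper ionophore — a bidentate
N,N-ligand that forms a tight 2:1 cuprous complex — drives copper into
*S. cerevisiae* cells, damages mitochondrial iron–sulphur clusters, and
thereby switches the iron regulons while the copper regulons respond to
copper itself. The package covers five analyses: replicate fold-change
calling on RPKM expression, the two-condition regulon fingerprint,
degenerate-consensus motif scanning with candidate-target nomination, the
Fra2-dependence partition, and the supporting biophysics (titration
stoichiometry and chelate geometry). A synthetic-data generator supplies
every input with known ground truth.

## Expression model and fold-change statistics

Abundances are RPKM, `count × 10⁹ / (length_nt × total_mapped_reads)`;
raw counts with lengths and per-sample totals convert via
`compute_rpkm`. Fold changes compare a test group against a reference
group (wild-type untreated) in an unpaired design: each test replicate is
divided by the reference-group mean, and the replicate ratios are
summarised by their mean and sample SD (n − 1). The reference mean is
floored (default 0.1 RPKM, flagged `low_reference`) so negligibly
expressed genes yield large-but-flagged folds rather than infinities.

Down-regulated genes (mean ratio < 1) are re-summarised on the reciprocal
scale — the mean and SD of `ref_mean / test_i` — so a 5-fold repression
reads as fold 5.0, and tabulated fold-decrease values are positive. The
*signed fold* used for plotting is +fold for up and −fold for down; by
construction no value lies strictly inside (−1, 1), which reproduces
symmetric linear fold axes without a log transform.

**Significance rule.** A change is significant when the fold change minus
one SD still exceeds the threshold (default 2) on the direction scale:
`fold − SD > 2`. This is the strict reading of "significant if 1 SD >
2-fold change": the whole 1-SD interval must clear the threshold. A
consequence worth noting: a 6.22-fold induction with SD 3.8 is still
significant (6.22 − 3.8 = 2.42 > 2), while a 2.0-fold change with SD 0 is
not (boundary excluded). Strong-responder tables (`threshold_table`,
default cutoff 4.5-fold) additionally require significance and sort by
descending fold.

**Fra2 partition.** For a gene with linear fold change S versus untreated
wild type, measured in the *fra2*Δ mutant untreated (S_u) and
ionophore-treated (S_t), the Fra2-dependent fraction of the response is

    f_dep = (S_u − 1) / (S_t − 1),

the share of the total induction already present as de-repression in the
untreated mutant. Signed folds are converted back to linear folds before
the ratio (−5 → 0.2), so the formula applies unchanged to repressed
genes. Genes with |S_t − 1| below a tolerance (default 0.1) are flagged
`undefined` rather than divided; fractions outside [0, 1] — possible
under noise — are flagged `out_of_range` but reported.

## Fingerprint and nomination

A fingerprint point is (x, y) = signed fold under copper + ionophore and
under copper alone, both versus untreated wild type; genes enter only if
they respond significantly ≥ 2-fold to the ionophore condition. Group
lines are unweighted ordinary least squares of y on x, fit separately
through the iron classes (Aft, Cth2) and copper classes (Ace1, Mac1);
Yap5 and unknown-class points belong to neither line. OLS on signed
linear folds (not log folds) was chosen because the fingerprint plots
fold changes directly and draws straight lines through them; the axis
convention is recorded in the output header.

Nomination joins the fingerprint with motif scans: candidate Cth2 targets
are unknown-class genes down ≥ 2-fold with ≥ 1 AU-rich element (ARE) in
the 3′-UTR; candidate Aft targets are unknown-class genes up ≥ 2-fold
with ≥ 1 Aft1 consensus site in the promoter. "Unknown" is operationalised
as absence from the supplied regulon annotation; the package ships the
regulon assignments of the named strong responders as a default table.

## Motif scanning

Consensi are token lists over IUPAC codes plus the two-letter Py
(pyrimidine, C/T) and Pu (purine, A/G) abbreviations; U canonicalises to
T. `expand_degenerate` enumerates the Cartesian product — the Aft1 site
PyPuCACCCPu yields 2×2×2 = 8 concrete words. The ARE's "octamer
derivative" set is read as the two contiguous 8-mers of the 9-mer
(TTATTTAT, TATTTATT): the minimal faithful reading of an octamer obtained
by dropping one terminal U; a user-supplied derivative set can replace it
(`extra_words`).

The ARE is an RNA element in the transcript, so it is scanned on the
stored (sense) strand of the 3′-UTR only; the Aft1 site is a DNA element
scanned on both promoter strands, with minus-strand matches reported at
the position of the reverse-complement instance on the stored sequence.
All overlapping occurrences are found; by default matches fully contained
in a longer match on the same strand are collapsed (a 9-mer ARE hit
implies its octamer hits; only the 9-mer is reported), with
`collapse=False` exposing everything. N never matches.

Region extraction uses 1-based inclusive annotation coordinates (GFF
convention) and reports 1-based positions. The promoter is 600 nt
immediately upstream of the annotated 5′ end on the gene's strand
(minus-strand promoters reverse-complemented); the 3′-UTR is the
annotated one when given, else 200 nt downstream. 600 nt reflects the
typical yeast intergenic scale and is configurable, since no window is
canonical. Regions running off a chromosome end are truncated and
flagged.

## Binding biophysics

The isotherm model is an overall 2:1 complex ML₂ with a single formation
constant β₂ = [ML₂]/([M][L]²); stepwise constants are not resolved
because only stoichiometry and tightness are at issue. Given totals, the
mass balance is solved by monotone bracketing (Brent) on free ligand;
convergence is judged on the bracket because at extreme β the raw
residual is dominated by cancellation in M_total − [ML₂] even when the
concentrations are correct to round-off. In the tight-binding limit
(β → ∞) the solution is `min(M_total, L_total/n)`, giving a sharp
breakpoint at 1/n equivalents. Absorbance is ε·[ML₂] + baseline.

`fit_breakpoint` fits a continuous two-segment line (rising segment +
plateau, plateau slope constrained ≥ 0) with the breakpoint chosen on a
coarse-to-fine grid over the interior of the data range (60 points, 4
refinements), minimising total SS; the smallest breakpoint wins SS ties.
Grid search rather than derivative methods keeps the fit robust on
8–12-point curves. The breakpoint is reported in metal:ligand
equivalents; its reciprocal is the ligand:metal stoichiometry, rounded to
the nearest half-integer with the raw value retained.

Metal quantification is Avogadro arithmetic: atoms per cell, atoms per fL
of aggregate cell volume, and the accumulated-metal:ionophore ratio under
the assumption that all added ionophore was taken up (unsubtracted and
flagged when no untreated baseline is supplied). The package provides
the calculator only; per-culture inputs are the user's.

## Chelate geometry

The bite angle is the N–Cu–N angle of one ligand's donor pair; each
chelate plane is defined exactly by Cu and its two donors (three points —
the minimal plane consistent with "Cu-ligand planes"; a fitted whole-ring
plane is deliberately not the default), and the dihedral is the angle
between plane normals folded into [0, 90]° so normal orientation is
immaterial. Donors are the N atoms within 2.5 Å of each Cu (covering
cuprous bis-diimine bond lengths with margin; configurable); they are
paired by ligand label when present, otherwise by exhaustive enumeration
of the three pairings of four donors minimising within-pair N–N distance.
Centres without exactly four donors are skipped and reported. Files with
several complexes report per-complex values and their mean, displayed to
0.1°. Collinear Cu–N–N triples raise an error (undefined plane).

The `gen_bischelate` constructor places the two donor pairs straddling +x
and −x with the second chelate plane rotated about x by the requested
dihedral; the construction is exact, so analysis recovers the inputs to
< 1e-6°, which the round-trip tests exploit over a grid of angles.

## Synthetic-data generator

The generator emulates the study conditions: five groups (wild type and
*fra2*Δ; untreated, copper-only, copper + ionophore) in triplicate.
Per-class fold ranges under the ionophore follow the printed extremes of
the strong-responder tables: Aft up 4–27×, Ace1 up 4–19×, Cth2 down
2–5×, Mac1 down 5–22×, Yap5 down 1.2–2× (modest). Copper-class genes
respond identically to copper alone; iron-class genes' copper-only
response scatters around 1 (SD 0.1) — reflecting the slight iron-regulon
repression seen under copper supplementation — which is what makes the
fingerprint's copper slope ≈ 1 and iron slope ≈ 0. Baselines are
log-uniform on 10–1000 RPKM.

Replicate noise is multiplicative log-normal parameterised by a CV
(default 0.1), with the log-mean chosen so the noise factor has
expectation exactly 1; cv = 0 therefore reproduces analytic expectations
bit-for-bit. The default CV is a calibration choice on the scale of the
published per-gene SDs, not a measured value. Iron-class genes carry a
Fra2-dependent fraction f drawn from `fra2_fraction_range`; their
expected untreated *fra2*Δ abundance is baseline × (1 + f·(effect − 1)),
and their treated *fra2*Δ abundance equals the full wild-type response.

Planted candidates (default 1 Aft-like, 9 Cth2-like — the scale of the
study's one new Aft target and nine Cth2 candidates) behave like their
class but are unannotated, and their fold ranges are bounded away from
the 2-fold nomination filter (Cth2-like 3–5× down, Aft-like 5–27× up) so
recovery tests measure the nomination logic rather than shot noise at the
threshold. Region backgrounds are i.i.d. uniform; a sequence carrying an
embedded motif is re-drawn until the planted instance is its unique hit,
so truth positions are exactly the recoverable hits, while unembedded
sequences keep their background hits at the analytic rate.

What the generator does **not** emulate: read-level sequencing (no
FASTQ), count overdispersion beyond log-normal, correlated replicates,
real yeast promoter composition (GC bias, nucleosome-free regions),
regulon cross-talk, or partial motif matches. Passing recovery tests
therefore demonstrate the correctness of the statistics and the joining
logic under the stated noise model — not that the pipeline would
reproduce the published gene lists from the deposited reads, which would
require the original data and genome annotation.

## Problem sizes and determinism

The default synthetic study is 106 genes × 15 samples; recovery checks
use 20 seeds (and 4 seeds × 5 planted fractions for the Fra2 grid), 2-kb
random sequences for scanner/oracle comparisons, and 11-point titration
curves — sizes chosen so the whole suite exercises every claim in a few
seconds on one core. All randomness flows through explicit
`numpy.random.default_rng` seeds; there is no global RNG state, and the
pipeline's tabular outputs are byte-identical across reruns of the same
config.

## Known limitations

- The significance rule is the strict reading of an ambiguous phrase;
  the alternative reading (mean − SD > 1, i.e. the interval excludes no
  change) would admit more genes. The rule is a single threshold on
  (fold − SD) and can be changed per call.
- `f_dep` is a ratio of noisy quantities; for weak responders it is
  unstable, which is why the `undefined` tolerance exists. It is reported
  per gene without error bars.
- The breakpoint fit assumes a single change point and a non-negative
  plateau slope; curves with gradual curvature from a soft formation
  constant shift the fitted breakpoint slightly below 1/n.
- CIF reading is minimal (atom sites + cell); symmetry expansion,
  disorder and anisotropic displacement are out of scope.
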