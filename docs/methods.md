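# Methods

## Assay model

*N*-acetyl-PABA excreted in urine carries an acetyl group drawn from the
hepatic cytosolic acetyl-CoA pool (the same pool that feeds de novo
lipogenesis). Its proton-decoupled ¹³C spectrum contains, besides the
aromatic PABA carbons, the acetyl C1 (carboxyl) and C2 (methyl)
resonances. ¹³C–¹³C scalar coupling between adjacent labeled carbons
(J = 51.0 Hz) splits each resonance into a doublet when *both* acetyl
carbons are ¹³C, so:

* C2 singlet ← [2-¹³C]acetyl (plus the 1.11% natural-abundance background),
* C2 doublet and C1 doublet ← the common [1,2-¹³C₂]acetyl pool,
* C1 singlet ← [1-¹³C]acetyl (plus background).

The two aromatic signals (defaults 130.85 and 121.57 ppm, two equivalent
carbons each) carry only natural-abundance ¹³C and anchor the absolute
enrichment scale. An empirical correction factor CF, measured once on a
nonenriched standard, absorbs everything that makes acetyl and aromatic
signal intensities non-comparable (stoichiometry is handled explicitly by
the per-carbon convention; T₁ saturation and nOe differences live in CF).
No relaxation physics is modelled anywhere else.

**Conventions that matter.**

* The per-carbon aromatic reference is `mean(two signal areas) / 2`. CF is
  defined against the same convention (`CF = per-carbon aromatic / C2
  total` of the reference), so the product is convention-free.
* The published form of the total-C2 equation carries a dangling ×100; it
  is implemented as `ratio × CF × 1.11` with enrichments in percent — the
  only reading under which the nonenriched standard returns 1.11%.
* Carbon-1 quantities are never referenced to the aromatic standard
  directly (the carbonyl's nOe/T₁ penalty differs from the methyl's);
  they are anchored to C2 through the shared [1,2-¹³C₂] doublet:
  `total C1 = total [1,2-¹³C₂] × C1/C1D`. Consequence: if the doublet is
  absent (no doubly labeled species), the [1-¹³C] excess is unidentifiable;
  the code returns natural abundance (zero excess) in that degenerate case
  and raises if the data claim doubly labeled enrichment without a C1
  doublet.
* Excess = total − 1.11 for singly labeled species, floored at zero with a
  logged warning (noise at low enrichment can push totals below
  background). The doubly labeled species needs no background correction:
  two adjacent natural-abundance ¹³C occur at ~0.012%, below any realistic
  noise floor.

## Integration

Each multiplet component is integrated by the trapezoidal rule over a
window of ± 0.1 ppm (configurable) around its predicted center — doublet
halves at center ± J/(2ν₀) = ±0.2535 ppm at 9.4 T — after subtracting a
linear baseline through the two window-edge strips (each strip 10% of the
window's points; wide strips suppress noise in the baseline estimate).

Lorentzian lines have heavy tails, so a finite window truncates real area
and the edge baseline subtracts a further tranche of the peak's own tail.
Both losses have closed forms for a Lorentzian of known linewidth: the
captured fraction is (2/π)·arctan(w/γ) and the baseline loss is the
strip-averaged tail level times the window length. Integrated areas are
divided by this combined factor, so a clean unit-area line integrates to
1.00 for any window ≳5 linewidths. Remaining cross-contamination between
components (a neighbor's tail inside a window, partially removed by the
baseline) is eliminated by two rounds of analytic mutual-tail
deconvolution over the eight known peak positions. Noise-free synthetic
spectra round-trip to ~0.02% per area after these corrections; without
them the small [1-¹³C] excess would carry a ~1% systematic error.

The uncorrected raw integral remains available
(`tail_correction=False`) and converges monotonically to the true area as
the window grows — the basis of a property test.

## Tracer scheme and attribution

Drinking water contains a 50/50 [U-¹³C]/unlabeled fructose mix and
[1-¹³C]glucose (99% isotopic purity). Glycolysis maps glucose C1 to
pyruvate C3 of one of the two triose units, so half of glucose-derived
acetyl is [2-¹³C] (absent cycling); fructolysis gives [U-¹³C]pyruvate and
hence [1,2-¹³C₂]acetyl from half of fructose-derived acetyl. Both labeled
fractions default to 0.5. The ÷0.99 purity correction is exposed as a
flag but **off by default**, matching the published contribution table,
which divides by exactly 0.5.

Attribution divides each diagnostic excess by its labeled fraction. For
glucose, pyruvate cycling makes the attribution interval-valued: the
observed [1-¹³C]acetyl could be cycled glucose label (upper bound, sum of
excesses) or Krebs-cycle-randomized label from either substrate (lower
bound, difference of excesses). The point estimate at cycling fraction
*f* interpolates affinely between the bounds and is clamped into them
when flooring makes the affine form dip below the lower bound.

Endogenous contributions are reported per bound (100 − fructose −
glucose). Note an internal inconsistency in the published summary for the
17.5%/17.5% cohort: from the printed inputs (excesses 1.1/2.6/5.3) the
endogenous values are 82.0/86.4 and the midpoint 5.2, whereas 82.2/86.6
and 5.0 are printed — reproducible only from unrounded inputs. The
package computes the self-consistent values; tests hold those entries to
±0.3 rather than imitating the rounding.

Group-level statistics (SEM propagation, t-tests) are out of scope; the
pipeline reports cohort means.

## Cycling simulator

Positional isotopomers are bitmask states (pyruvate 8, acetyl 4,
oxaloacetate 16). Atom maps:

* PDH: pyruvate C1 → CO₂; C2 → acetyl C1; C3 → acetyl C2.
* PC: pyruvate C1–C3 → OAA C1–C3; CO₂ (unlabeled) → C4.
* Citrate-synthase turn: prior OAA C1 and C4 leave as the turn's two CO₂;
  prior C2 → new C2, prior C3 → new C1, acetyl C2 → new C3, acetyl C1 →
  new C4.
* Fumarate/succinate symmetry: C1↔C4, C2↔C3 exchanged with probability ½.
  The OAA pool is stored post-scrambling, so the PEPCK/malic-enzyme step
  (both lose C4 and are treated jointly) draws from the scrambled pool;
  conventions that scramble after rather than before decarboxylation
  differ only in bookkeeping.

Fluxes are normalized to citrate synthase = 1. The acetyl pool closes
without an explicit export flux: citrate synthase consumes the pool and
endogenous unlabeled production supplies 1 − pdh_flux; the sampled
N-acetyl-PABA enrichment is the inflow-weighted pool composition, which
is independent of any export flux value. The pyruvate pool must be fed at
least as fast as PDH drains it (validated); surplus leaves as unlabeled
disposal.

The default mode is **linearized** (single labeled molecule per
trajectory): condensation partners of labeled molecules are unlabeled,
exact to first order in the excess enrichments — the right regime for
excesses of a few percent, and the regime in which the key structural
fact holds: *label that has passed a citrate-synthase turn can only
return to acetyl singly labeled*, so the [1,2-¹³C₂] species is an
uncontaminated fructose reporter. A full bilinear ("joint") mode exists
for cross-checking the approximation. The steady state is a fixed point
of the flux-weighted update, iterated to 1e-10 with a 10⁵-iteration cap
(the update is a contraction; convergence takes tens of iterations). No
randomness is involved.

**Provenance.** Because the linearized system is linear, each feed
substrate's labeled contribution is solved independently, and the
"direct" channel — label reaching acetyl without any citrate-synthase
turn, i.e. first-pass PDH plus direct PC→fumarate→PEPCK cycling — is
isolated by solving the same system with turn feedback removed. A
substrate's *traceable* contribution is its direct-channel labeled acetyl
divided by its labeled fraction; label randomized by the cycle cannot be
attributed to a parent substrate even in principle. Under this definition
the simulator confirms, for arbitrary mass-balanced flux configurations:
the fructose estimate equals the truth exactly, and the glucose truth
lies within [lower, upper].

A truncated propagation (`truncated_acetyl_flux`) bounds the number of
"cycle events" per labeled trajectory, where one event is either a
citrate-synthase turn or a PEPCK transit (both must be counted, otherwise
trajectories are unbounded). It is checked exactly against exhaustive
recursive enumeration of labeled-molecule trajectories and converges to
the steady state as the cap grows.

**Default flux scenario** (configurable; the underlying in-vivo fluxes
are not identifiable from four acetyl isotopomers): pdh = 0.15, cycling
= 3.0, anaplerotic inflow = 2.0, feed (glucose 0.25, fructose 0.50,
unlabeled 0.30). High cycling and anaplerosis relative to citrate
synthase are characteristic of liver; under this scenario ~49% of
[1-¹³C]acetyl arises from directly cycled [3-¹³C]pyruvate and the rest
from randomized Krebs-cycle isotopomers, which is the justification for
quoting the midpoint (f = 0.5) glucose estimate.

## Synthetic data

The generator inverts the quantification chain exactly: enrichments →
areas (per-carbon aromatic area = 1 at natural abundance; per-signal
attenuation factors 0.5 for the carbonyl, 0.9 for the methyl, 1.0 for
the aromatics emulate T₁/nOe qualitatively and cancel through CF) →
spectra as sums of Lorentzians (default FWHM 0.5 Hz, the line broadening
applied to the real data; doublet halves carry half the doublet area at
±J/2ν₀) plus seeded white Gaussian noise scaled to the maximum clean
intensity (default 0.2%). The axis samples ±1 ppm regions around the
peaks at 10 points per linewidth; acetyl chemical shifts (173/23 ppm) are
synthetic conventions, as the real shifts are not tabulated here. An
optional N-acetyl-PAH interference line can be placed downfield of each
acetyl component; at the default window geometry the only clear location
is midway between singlet and doublet windows (~0.127 ppm offset).

Cohorts draw per-animal excesses from independent normals around the
ground truth (clipped at zero), defaults (0.1, 0.1, 0.2)% SD for
([1-¹³C], [2-¹³C], [1,2-¹³C₂]) — the published cohort standard errors —
plus one nonenriched reference spectrum, with the seed recorded in the
manifest.

What the generator does **not** emulate: time-domain acquisition, phase
and baseline-roll artifacts, the reported extra broadening of one
aromatic signal (available as `linewidth_factor_35` but off by default),
natural-abundance ¹³C–¹³C satellites (~0.01%, far below noise), and any
real-sample matrix effects. Passing tests therefore demonstrate
correctness of the quantification arithmetic and robustness to white
noise and known interferences — not robustness to phasing or baseline
pathology in real spectra.

## Numerical choices

* Fixed-point tolerance 1e-10, cap 10⁵ iterations; distribution sanity
  checked to 1e-9.
* Integration: window 0.1 ppm, edge strips 10% of window points, two
  neighbor-deconvolution rounds; all analytic corrections assume the
  configured Lorentzian linewidth.
* Monte-Carlo recovery checks use 500 replicates of 4-animal cohorts in
  antithetic pairs (mirrored animal deviations), so the bias estimate is
  not dominated by residual sampling noise at this replicate count.
* Problem sizes throughout (spectra of ~16k points, cohorts of 4,
  500 replicates, 100 random flux draws) are chosen as the smallest that
  make the statistical statements meaningful.

## Known limitations

* CF transfers T₁/nOe corrections from the reference to samples; if
  acquisition conditions differ between them, the enrichment scale is
  biased — a property of the assay, not just the implementation.
* The [1-¹³C] excess is the smallest quantity and inherits relative error
  from three area ratios; at 0.4% excess, a 0.5% systematic area error
  already costs ~2% relative.
* The cycling simulator treats one well-mixed cytosolic/mitochondrial
  system; compartmentation of acetyl-CoA pools and CO₂ refixation are not
  modelled, and glutamate/glutamine isotopomers (which would identify the
  fluxes) are out of scope.
* The linearized mode fails loudly if label content is pushed far beyond
  the low-enrichment regime; use the joint mode to inspect such regimes.
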