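# Methods

This note records the models, numerical choices and limitations behind
`sxmerge`. It documents what the code computes; every empirical statement
here is reproduced by the test suite or by `scripts/acceptance.py`.

## Data model and symmetry

Reflection files are a plain-ASCII dialect of the XDS_ASCII.HKL layout:
`!KEY= value` header lines (unit-cell constants, space-group number,
wavelength, Friedel's-law flag), `!END_OF_HEADER`, whitespace-delimited
records `H K L IOBS SIGMA [PHI]`, `!END_OF_DATA`. Unknown header keys are
ignored; observations with σ ≤ 0 are dropped and counted. When the
Friedel flag is absent, Friedel pairs are treated as equivalent — the
default non-anomalous MX case.

Symmetry comes from an explicit bundled operator table (JSON, translations
in twelfths) covering a practical MX subset: P1, P2₁, C2, P2₁2₁2₁, C222₁,
P4₃2₁2, P6₁22, P2₁3. Other group numbers raise a clear unsupported-group
error. The asymmetric-unit representative of a Miller index is the
lexicographically greatest tuple over all point-group images (plus Friedel
mates when merged non-anomalously). Any fixed convention would do — only
equality of representatives is ever used — and the choice makes the
reduction a pure integer `argmax`, verifiable by brute-force orbit
enumeration (and, in the tests, against gemmi). Systematic absences use
the standard criterion: an operation fixes the index with a non-zero
phase shift. Completeness denominators enumerate the index box bounded by
|h| ≤ a/d_min (an exact bound, since the reciprocal vector's projection on
the direct axis **a** is h/a) and reduce it to unique non-absent
representatives.

## Scaling engine

Each dataset j gets a multiplicative scale k_j and a relative isotropic
B-factor relative to a fixed reference (k = 1, B = 0):

    I'_i = I_i / g_j(s²),   g_j(s²) = k_j · exp(−2 B_j s²),   s = 1/(2d).

Refinement is alternating weighted least squares in log space. With
w_i = (I_i/σ_i)² (capped at 10⁶, positive intensities only):

1. merged log-intensities per unique h: the w-weighted mean of
   ln I_i − ln g_j;
2. per dataset: exact WLS of ln I_i − m_h on (1, s²), giving
   (ln k_j, −2B_j).

Both half-steps minimise the same objective Σ w (ln I − ln g − m)², so it
is non-increasing — asserted per iteration in the tests. Iteration stops
when the largest relative scale change drops below 1e−4; the cap is 100
sweeps, because the alternating scheme typically needs 50–70 sweeps to
reach that tolerance on a 10-dataset ensemble (each sweep is milliseconds).
With fewer sweeps the scales are visibly under-converged (≈4% error where
the converged solution is ≈0.1%).

Datasets sharing fewer than 10 unique reflections with the rest of the
ensemble (or with fewer than 3 positive intensities) are excluded as
`unconnected` rather than failing the run.

The final merge is the inverse-variance weighted mean of the corrected
intensities per unique reflection; negative merged intensities are
retained. Statistics use resolution shells holding equal numbers of
observed unique reflections (10 by default):

* **R_meas** = Σ_h √(n_h/(n_h−1)) Σ_i |I_i − ⟨I⟩_h| / Σ_h Σ_i I_i over
  uniques with n_h ≥ 2;
* **CC1/2**: Pearson correlation of half-set means from a seeded random
  split of each unique's observations (default seed 13; the extra
  observation of an odd multiplicity goes to half A); shells with fewer
  than 3 splittable uniques report it as undefined, not zero;
* **completeness**: observed uniques over the symmetry-expected count in
  the shell's d-window;
* **I/σ** from the merged values.

The engine reproduces the decision-relevant outputs of a general-purpose
scaler (ranking, filtering, shell statistics); equivalence with any
external program's exact shelling or rejection rules is not claimed.
Zero-dose extrapolation, per-observation outlier rejection and σ
re-inflation of merged values are out of scope.

### Wilson B and low-resolution R_meas

The per-dataset Wilson B comes from the least-squares slope (−2B) of
ln⟨I⟩ vs ⟨s²⟩ over equal-count shells at d < 4.5 Å; datasets with fewer
than two usable shells are `undefined` and ranked last as reference
candidates. The ranking statistic is the mean internal R_meas of the three
lowest-resolution shells (of 10 equal-unique-count shells over the
dataset's own range); datasets with no internal symmetry mates there rank
last (+∞).

## Error model and ISa

Per dataset, residuals δ_i = (I_i − ⟨I⟩_h)·√(n_h/(n_h−1)) are taken
against the **pooled** merged means of the whole scaled ensemble. A 10°
wedge rarely contains 30 internal groups of multiplicity ≥ 3, so a
within-dataset fit would be undefined for nearly every miniset; pooling
matches how multi-dataset scalers compute per-input-file error models.
Observations in groups with total multiplicity ≥ 3 are pooled into 10
equal-count bins **keyed on the group mean ⟨I⟩** — binning on the noisy
observation itself is an errors-in-variables trap that washes out the I²
term exactly for the high-error datasets the filter must catch. Per bin,
the mean squared residual is regressed on (⟨σ_raw²⟩, ⟨I²⟩) by non-negative
least squares, each bin weighted by √n/RMS² (the sampling error of a mean
square scales with its value; unweighted, the strongest bin dominates and
the two nearly collinear columns cannot be separated). Then
a = c₁, b = c₂/c₁ (both floored at 1e−8) and ISa = 1/√(a·b). Fewer than 30
usable groups, or a degenerate design, yields an "undefined" model, which
the ISa filter treats as failing. The fitted model is used only for
filtering; merged σ values are not re-inflated.

## Selection stages

* **Indexing consistency**: all six cell parameters within 5% relative of
  the reference (user-specified, else the first dataset), and equal
  space-group numbers. Reason codes: `bad_cell`, `bad_spacegroup`.
* **ISa filter**: keep ISa ≥ cutoff (default 3.0, boundary inclusive);
  undefined models rejected. If the filter would leave fewer than two
  datasets, the stage is marked failed and the cascade continues from the
  previous accepted set.
* **Cell clustering** (n < 200): Ward linkage on Euclidean distances
  between the cells' face-diagonal 3-vectors
  (√(a²+b²+2ab·cos γ), √(b²+c²+2bc·cos α), √(c²+a²+2ca·cos β)), tree cut
  at 2.0 (Å of resultant-vector space), most populated cluster kept. For
  n ≥ 200 a per-parameter Gaussian filter keeps datasets with all six
  parameters within mean ± 1.5σ; the parameters are filtered
  independently for transparency.
* **pCC clustering**: per dataset, mean intensity per unique in the 4–8 Å
  window (medium resolution — low-resolution shells correlate deceptively
  through a few strong reflections, high-resolution shells through many
  weak ones); Pearson correlation over the uniques common to each pair
  (i < j, mirrored; diagonal 1; pairs with < 3 common uniques get CC 0 and
  a logged flag, penalising weak connectivity instead of erroring).
  Average-linkage clustering on a dissimilarity, cut at 0.8, most
  populated cluster kept. Two dissimilarities are offered:
  `rows` (default) — one minus the correlation between two datasets' CC
  profiles, computed with the two self entries excluded so the unit
  diagonal cannot anti-correlate otherwise identical profiles; and
  `sqrt1mcc2` — √(1 − CC²) directly per pair.
* Ties for "most populated" prefer the cluster containing the scaling
  reference, then the cluster with the lexicographically smallest member.

Cell and pCC selection both consume the ISa-selected set; neither consumes
the other's output, so the accepted sets form a subset chain from the
indexing stage through ISa into each branch.

## Diagnostics

**Preferred orientation.** After merging, the per-reflection multiplicity
distribution should be roughly symmetric when crystal orientations are
uniform; orientation bias skews it and carves persistent blind zones. The
report histograms multiplicities — including, when the expected unique
count is supplied, never-observed reflections at multiplicity 0 — and
flags |Fisher–Pearson skewness| > 0.5. The threshold is the conventional
moderate-asymmetry boundary and is configurable; at desk-scale problem
sizes (~10³ uniques with spatially correlated coverage) the statistic has
a broad null distribution, so only strong bias flags reliably.

**Anisotropy.** An internal estimator, not a re-implementation of any
external program: unique reflections whose reciprocal-lattice vector lies
within 30° of a*, b* or c* (either hemisphere; true reciprocal axes of the
reference cell, not Cartesian axes) are binned into 5 equal-count shells,
and the directional limit is where the shell-mean merged I/σ first drops
below 1.5, linearly interpolated between shell midpoints; if it never
drops, the best shell edge is reported. Ellipsoidal anisotropy fitting is
out of scope.

## Pipeline, schedule, persistence

One run writes, per stage: the merged HKL artifact
(noSelect/ISa_Select/Cell_Select/pCC_Select), a statistics JSON, dendrogram
JSON for the clustering stages, multiplicity TSVs, and a single
`report.json` with the full accept/reject ledger (machine-readable reason
codes), scale and error models, statistics and diagnostics. All JSON is
key-sorted and seeds are explicit, so identical inputs and configuration
give byte-identical reports. A failed stage logs, is marked failed, and
downstream stages consume the last successful accepted set.

Incremental mode counts minisets as they appear and triggers a full
re-merge of everything seen whenever the count hits
{10, 20, …, 100} ∪ {120, 140, …, 200} ∪ {250, 300, …, 800} — strides 10,
20 and 50, 27 triggers in total; the continuation strides follow the
natural arithmetic reading of the schedule and are overridable in the
configuration. State (count, seen files, last trigger) is rewritten after
every change, so a crashed session resumes without re-triggering past
merges. Full re-merge at each trigger is the simplest consistent policy;
incremental updates of a previous merge are not attempted.

## Synthetic ensembles

The generator emulates the data regime the cascade is built for — many
small wedges from microcrystals — with ideal monochromatic rotation
geometry: spindle along laboratory z, beam along x, no mosaicity or
partiality (downstream logic consumes only intensity lists, never
partiality). True intensities follow the acentric Wilson model
I_h = C·exp(−2B·s²)·E_h, E_h ~ Exp(1) (defaults C = 1000, B = 15 Å²,
cell 40×50×60 Å C222₁, d_min = 3 Å, 10° wedges). A reflection is observed
when a solution of A·cos φ + B·sin φ = C (the Ewald crossing of its
rotating reciprocal vector; every point-group and Friedel mate is tested
separately) falls inside the wedge; vectors too close to the spindle axis
(no real solution) are blind.

Per dataset: k_j ~ U(0.5, 2), B_j ~ U(0, 10) Å²; counting-model noise
σ² = I/gain + floor (gain 1, floor 25); cell jitter σ = 0.05 Å/°, plus a
per-cluster additive cell offset. Non-isomorphism: each non-reference
cluster's truths are multiplied by exp(ε), ε ~ N(0, τ²); for the default
minority cluster τ = 2.0, which puts the realised intensity-space
cross-cluster pCC near 0.3 (the log-space correlation is
var/(var + τ²)-shaped with var(log E) = π²/6; `tau_for_cc` inverts it).
Low-ISa datasets multiply the signal by (1 + η), η ~ N(0, σ_sys = 0.5),
unreported in σ — the fitted ISa lands near 1/σ_sys = 2, below the 3.0
cutoff. Low-ISa flags are drawn from the majority cluster when possible so
that systematic error and non-isomorphism remain separable failure modes.

Preferred orientation: the crystal c* axis is drawn from a von
Mises–Fisher distribution (concentration κ; κ = 0 uniform) around the
**beam** axis — the fixed-target normal — and every wedge starts at the
same spindle angle. Both details matter: with per-dataset random start
angles, or bias around the spindle axis itself, the Ewald-crossing
probability is orientation-independent and no bias would ever be visible
in the multiplicity distribution.

The showcase recipe (`showcase_config`) is 100 datasets, 10° wedges, 80/20
majority/non-isomorphous clusters with 20% of datasets low-ISa — i.e. 60%
clean majority — mirroring a realistic fixed-target experiment at desk
scale.

### What the generator does not emulate

Mosaicity, partiality, absorption, radiation damage, detector effects,
indexing ambiguities and real non-isomorphism's structured (rather than
log-normal i.i.d.) intensity differences. Passing tests therefore
demonstrate the *logic* of the cascade — that each filter removes what it
is designed to remove under its own model — not performance on any real
beamline dataset. Problem sizes in tests (10–80 datasets, ~1–3·10³ unique
reflections) are chosen so the full suite runs in well under a minute per
module while every statistic stays in its asymptotic regime.

## Degenerate inputs and tie-breaks

σ ≤ 0 observations are dropped on read and counted; empty minisets refuse
to write; a constant multiplicity distribution has skewness 0 by
definition; a constant-intensity error-model fit returns "undefined"
rather than raising; Wilson-B ties between reference candidates break by
dataset id; cluster-size ties prefer the reference's cluster; R_meas
ranking is stable for ties and +∞ sorts last; the CC1/2 split, the
cascade seed and the generator seed are all explicit parameters.
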