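# Methods

## The measurement this package models

Two-photon phosphorescence lifetime microscopy (2PLM) with a plasma-borne
oxygen probe measures intracapillary pO2 at single points: each visit to a
point repeats 1000 cycles of 10 µs excitation and 290 µs of photon
counting (300 ms per point), and the points of a field are revisited every
~8 s for ~10 minutes.  The pooled arrival-time histogram of a visit decays
with the probe's phosphorescence lifetime τ, which collisional quenching
by O2 shortens according to the Stern-Volmer relation

    1/τ = 1/τ0 + kq · pO2

with τ0 the zero-oxygen lifetime and kq the quenching constant, both
calibrated per dye batch by an oxygen titration.  Because red blood cells
exclude the dye, the same cycles read as an intensity time course in
which each RBC passage is a dip: counting dips gives flux (RBCs/s), and
dip dwell time with an assumed RBC path length gives speed.  Between
RBCs, intravascular pO2 relaxes from its near-RBC value toward the
surrounding tissue value (the erythrocyte-associated transient, EAT);
pooling photons by distance-to-nearest-RBC and reading the far plateau
estimates tissue pO2.  A stall is a maximal run of visits with zero flux;
stall pO2 below 10 mmHg is classified hypoxic (cell respiration becomes
oxygen-limited), below 5 mmHg severe.

## Lifetime fitting

Per visit, arrival times are re-referenced to the end of the excitation
window, the first 5 µs discarded (electro-optic modulator response), and
the remainder pooled into 0.5 µs bins (570 bins).  The model
`A·exp(−t/τ) + B` is fitted by Poisson maximum likelihood (the correct
noise model for photon counting; least squares is available), with τ
initialized from the log-linear slope of background-subtracted counts, A
from the first retained bin and B from the last 10% of bins.  The
optimizer works in (log A, log τ, B ≥ 0); convergence is judged by the
projected gradient, since a stalled line search at the optimum is not a
failure.  Visits with fewer than `min_photons` (default 500) photons are
flagged not-converged — the quality threshold standing in for "low
signal" rejection, for which no published number exists.  Lifetimes
slightly above τ0 clip to pO2 = 0 with a flag; lifetimes more than 5%
above τ0 are out-of-range (NaN).

## Flux segmentation and its quality control

Otsu's threshold is computed on the per-cycle counts with one histogram
bin per observed value and ties broken toward the lower threshold; cycles
at or below it are RBC, and maximal runs shorter than `min_dip_cycles`
(default 3, ~1 ms) are discarded as shot noise.  Two findings from
simulation shaped the defaults beyond that textbook recipe:

- **Smoothing (default 5 cycles, 1.5 ms, edge-corrected moving average).**
  On raw counts at realistic rates (~20 photons/cycle, dips to ~2),
  shot noise creates ~10 spurious sub-millisecond runs per 1000-cycle
  visit, so per-visit dip counts never match the schedule exactly; a
  5-cycle average removes them while leaving multi-ms dips intact.
  Partial dips at the trace edges count as passages; 1-2-cycle edge
  slivers that smoothing would dilute are rescued from the raw counts at
  half the threshold.
- **Dip-contrast gate.**  Otsu always finds *a* split, even of a
  unimodal noise trace, and its goodness measure (between-class /
  total variance) is ≈0.6 for any split of non-constant data — it does
  not discriminate real dips from noise.  The gate therefore requires
  the class contrast to exceed 3× the plasma shot noise
  (`(µ_plasma−µ_RBC)/sqrt(µ_plasma/w)`); traces failing it carry no RBC
  evidence and are returned all-plasma.  For a capillary with otherwise
  clear dips such a visit is exactly what a stall looks like and passes
  QC as a zero-flux observation; a capillary that *never* shows dip
  contrast fails QC wholesale (`no_flux_contrast`), the quantitative
  stand-in for manual "clear dips" pre-selection.  A deep-dip fallback
  (runs at ≤ half the mean level, impossible from shot noise at these
  rates) rescues tiny truncated dips that lose the Otsu variance contest.

QC also rejects visits whose mean counts fall below half the capillary's
session median (probe loss / focus drift).  Speed is the assumed RBC path
length (default 6 µm, an explicit, reported assumption — a point
measurement cannot observe it) divided by the median dip dwell time.

## EAT and tissue pO2

Plasma-phase photons of qc-passing flowing visits are pooled across
visits; each photon's distance is the time to the midpoint of the nearest
RBC passage times the RBC speed, binned at 1 µm.  Per-bin decays are
fitted as above; the tissue estimate pools all sufficiently filled bins
beyond the plateau cutoff — the larger of 10 µm and half the median
inter-RBC distance.  With the simulator's EAT length constant of 10 µm, a
cutoff near its lower bound still contains ~25% of the gradient, which
can bias the estimate upward by ~2 mmHg when the inter-RBC-distance
estimate is unlucky; a cutoff of ≥3 length constants removes this, and
the recovery benchmark's conditions (flux 5 RBC/s, 24 visits) make the
data-driven cutoff land safely far out.

## Stall analysis

Maximal runs of zero-flux qc-passing visits form events; qc-failed visits
break runs (a stall cannot be asserted across unmeasurable visits) and
flag adjacent events `boundary_uncertain`.  Consecutive zero-flux visits
are treated as one continuous event although the ~8 s cadence cannot
exclude brief intervening flow; per-event visit lists are retained.
Event pO2 is the mean over event visits, represented at t = 0 in
peri-stall alignment; offsets ±k are the k-th qc-passing visits before
onset/after the end.  Hypoxia thresholds are strict (`< 10`, `< 5` mmHg).
The stall-vs-tissue comparison fits OLS per group (awake / anesthesia
label carried, not interpreted).  Neighbor effects compare each
non-stalling capillary's visits concurrent with any stall (same visit
sweep) against visits concurrent with none, giving ∆pO2 and a flux
ratio, regressed on 3D Euclidean distance between measurement points
(the in-plane-vs-3D choice is undocumented in the field; 3D is used and
flagged).

## Vessel geometry

Subvolumes of 75 voxels in each direction (151³ interior) around a
measurement point are median-filtered (3×3×3, reflective boundaries),
binarized by the same Otsu implementation (256 uniform bins for float
volumes), and skeletonized by 3D thinning.  Local vessel density is the
histogram of anisotropy-corrected Euclidean distances from the point to
every vessel voxel, 1 µm bins, arbitrary units; its total equals the
vessel voxel count exactly.  Density uses the full binarized mask, not
the skeleton (the skeleton is exposed for inspection).  Nearest
arteriole/venule distances go to the nearest labeled voxel (vessel edge).
Known resolution limits: the median filter erodes the one-voxel shell of
tubes of radius ≲3 µm (Dice ~0.84 there, ≥0.95 from radius 4 µm), and
thinning erodes open tube ends by roughly the tube radius.

## The synthetic-data generator

The generator emulates, with known ground truth: Poisson photon streams
whose decay lifetime encodes pO2 through an invertible Stern-Volmer
calibration (simulator constants τ0 = 40 µs, kq = 5·10⁻⁴ /(µs·mmHg),
spanning τ ≈ 13-40 µs over 0-100 mmHg — analysis code never assumes
them); dye-exclusion dips (default ~20 photons/cycle plasma, ~2 in-dip:
deep exclusion, as real dips are) at programmable flux, transit time and
speed, with Poisson or regularly spaced arrivals; stalls as instantaneous
steps to a lower equilibrium pO2 (the revisit cadence cannot constrain
kinetics); an exponential EAT profile from the near-RBC value to the
tissue value (length constant 10 µm; the real profile's shape is not
parameterized in the literature); optional dark counts, uniform over the
collection window; an optional neighbor coupling (pO2 offset and flux
scaling attenuating exponentially with distance from a concurrently
stalled capillary); and tube-network angiograms (cylinders + blur +
noise) with truth masks, centerlines and arteriole/venule labels.
Arrival times are quantized to the 0.5 µs decay bin, mirroring TCSPC.
An expected-value mode emits fractionally weighted photons carrying exact
expected bin contents, so noiseless tests check closed forms rather than
Monte-Carlo luck.

What the generator does *not* emulate — and hence what passing tests do
not establish about real data: motion and focus drift, probe
photobleaching, capillary diameter change and hematocrit phase
separation, network flow redistribution, multi-exponential decay from
mixed compartments, and detector afterpulsing.  Default physiological
values (flowing pO2 ~45 mmHg, tissue ~28 mmHg, flux 5-25 RBC/s, speed
0.5-1.5 µm/ms, transit 4-8 ms) sit in the range reported for awake mouse
cortical capillaries.

## Benchmark problem sizes

The recovery benchmarks used by `scripts/acceptance.py` and the
acceptance tests run at: pO2 grid {5,10,20,40,80} mmHg × 50 visits plus
3 photon budgets × 40 visits; flux {2,5,10,20} RBC/s × 50 visits with
regularly spaced transits (Poisson coincidences are a genuine resolution
limit, quantified separately) plus a 50-trace exhaustive-Otsu
cross-check; EAT tissue {10,25,40} mmHg × 24 visits (>10⁵ far-field
photons per level); 200 independent cohorts of 32 single-visit stalls
with 13/32 assigned hypoxic; 200 regression cohorts of n = 32 with
generative slope 0.79, intercept −4 and scatter sized for R² = 0.47; and
tube-fixture geometry checks with anisotropic voxels.
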