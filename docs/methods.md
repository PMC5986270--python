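# Methods

`protonflux` quantifies proton-coupled lactate transport experiments: it
turns raw ratiometric-dye or microelectrode recordings into calibrated pH
and proton-concentration traces, extracts transport rates around substrate
application and withdrawal, converts them to trans-membrane proton fluxes
via the cell's intrinsic buffer capacity, measures carbonic-anhydrase (CA)
activity from ¹⁸O isotope-exchange mass spectrometry, and counts stained
nuclei as a proliferation readout.  Because no raw recordings ship with the
package, every estimator is validated against a seeded synthetic-data
module that generates inputs with known ground truth.

## Signal model and calibration

**Ratiometric dye.**  A SNARF-type indicator's emission ratio R maps to pH
through a Boltzmann sigmoid

    R(pH) = (A1 − A2) / (1 + exp((pH − x0)/dx)) + A2,

with acidic plateau `A1`, alkaline plateau `A2`, midpoint `x0` (≈ dye pK_a)
and width `dx` (pH units; a negative `dx` flips the orientation).  During a
nigericin/high-K⁺ clamp the cell is held at known pH values (default steps
6.0–8.0); each step's plateau ratio is estimated by mono-exponential
regression and the sigmoid is fitted by least squares.  The fit is started
from a variable-projection grid search — the model is linear in
`(A1 − A2, A2)` once `(x0, dx)` are fixed — and refined with
`scipy.optimize.curve_fit`, which makes it robust to poor starting values.
Recorded ratios are inverted with the exact algebraic inverse

    pH = x0 + dx · ln((A1 − A2)/(R − A2) − 1),

valid strictly between the plateaus.  Ratios that graze a plateau closer
than ε = 1e-9 (noise can touch the asymptotes) are clamped inward and
flagged in the output metadata; ratios on or beyond a plateau are an error
naming the offending sample.

**Microelectrode.**  Electrode potential maps to pH by the ordinary
least-squares line `pH = intercept + slope·V_e`, calibrated from baths of
known pH (two baths give the exact interpolant).  Proton concentration is
`[H⁺] = 10^(−pH)·10⁹ nM` per sample, so rate comparisons are not distorted
by the logarithmic pH scale.

**Steady states.**  Plateaus are the asymptote of
`y(t) = y_ss + (y0 − y_ss)·exp(−t/τ)` fitted on time measured from the
segment start (hence time-shift invariant).  When the optimiser fails, or
the fitted τ exceeds three times the segment span, or the asymptote falls
outside the observed range by more than half the data spread — all signs
that the plateau was never observed and the asymptote is extrapolation —
the mean of the final quartile of samples is used instead and the fallback
is recorded.  This guard matters in practice: a mono-exponential fitted to
a *flat, noisy* baseline is weakly identified and can drift its asymptote
far off the data.

## Rates, buffering and proton flux

Transport rates are linear-regression slopes, reported per minute.  Two
modes exist: `fixed-window` (OLS over a stated window anchored at the
event edge) and `max-slope` (a window of length w sliding one sample at a
time; the slope of maximal magnitude wins, ties to the earliest window).
Windows are time-based, so irregular sampling is handled; each window
needs ≥ 3 samples.  A flat window reports slope 0 with r² defined as 0.

Two systematic effects of window choice are worth knowing.  For a
mono-exponential response with time constant τ, the OLS slope over a
window w starting at the onset underestimates the initial slope by
≈ w/(2τ); keeping w ≲ τ/10 keeps this bias near 5%.  Conversely,
`max-slope` on noisy data is an extreme-value statistic and is biased
*upward* when the per-window slope noise is comparable to the true slope;
short windows make this worse.  The recovery suite therefore uses
onset-anchored fixed windows of τ/10 averaged over many simulated cells
(noise in a linear estimator is zero-mean, so the average isolates the
bias), while the worked analyses use the 30 s max-slope window typical of
imaging work, where the window-averaging bias cancels out of
between-condition ratios.

**Buffer capacity.**  The intrinsic (non-CO₂) buffering power is measured
from a terminal 5% CO₂/10 mM HCO₃⁻ pulse.  Dissolved CO₂ is fixed by the
extracellular equilibrium, `[CO₂] = [HCO₃⁻]_o / 10^(pH_o − pK′)`, and —
with CO₂ membrane-equilibrated — Henderson–Hasselbalch gives
`[HCO₃⁻]_i = [CO₂]·10^(pH_i − pK′)`.  Since the experiments run nominally
CO₂/HCO₃⁻-free outside the pulse, the pre-pulse intracellular bicarbonate
is taken as 0 mM, so Δ[HCO₃⁻]_i equals the pulse steady-state value and

    β_i = Δ[HCO₃⁻]_i / |ΔpH_i|   (mM per pH unit).

β_i is the standard orientation of the definition (mM of acid equivalents
per pH unit); a |ΔpH| below 0.01 is refused as unresolvable.  `pK′`
defaults to 6.1 at room temperature (the physiological-chemistry
convention) and is configurable.  The CO₂-dependent buffering term is
deliberately omitted, matching the nominally CO₂-free protocol.

**Proton flux.**  `J_H = |ΔpH/Δt| · β_i` in mM/min; the construction
asserts the identity exactly, and the acidification/alkalinisation sign is
carried as direction metadata rather than in J_H itself.

**Injection dilution.**  Injecting volume V at concentration C into an
effective free volume V_f yields `C·V/(V_f + V)`; for an oocyte
V_f ≈ 0.35 µl.  Whether the injected volume belongs in the denominator is
immaterial at reporting precision (29.2 vs 31.5 mM both read 30 mM at one
significant figure); the implementation includes it because the injected
bolus dilutes into the combined volume.  A helper rounds to n significant
figures for reporting.

## ¹⁸O-exchange CA activity

The assay follows the loss of ¹⁸O from doubly labelled ¹³C¹⁸O₂ across
m/z 49 → 47 → 45.  The statistic is the log enrichment
`LE = log₁₀(100·a₄₉/(a₄₉+a₄₇+a₄₅))` — log₁₀, so a pure m/z-49 sample reads
LE = 2 on the conventional percent scale — which is invariant to overall
abundance scaling and decays linearly for first-order exchange.
Depletion rates are OLS slopes of LE per minute, taken before (uncatalyzed)
and after (catalyzed) lysate addition; the addition time is a required
input.  Enzyme units follow the Badger convention — one unit is 100%
stimulation of the uncatalyzed depletion — i.e.
`U = |r_cat|/|r_uncat| − 1`, with `units/ml = U / sample volume`.  The
default sample volume is 0.08 ml (20 oocytes lysed in 80 µl saline); which
volume normalises units/ml is exposed as a parameter since conventions
differ.  Rates of opposite sign are an assay error; a catalyzed rate
slower than the uncatalyzed one gives a negative U that is flagged, not
clipped.

The simulation stand-in is the first-order cascade
`d49/dt = −2θ·49, d47/dt = 2θ·49 − θ·47, d45/dt = θ·47` (two exchangeable
¹⁸O atoms, then one), solved in closed form, with θ stepping to
θ·(1+U_true) at addition.  In this model LE is *exactly* linear with slope
−2θ/ln 10, which doubles as a mutual-consistency check between generator
and statistic.  The full exchange chemistry (species-specific
hydration/dehydration, pH dependence) is intentionally not modelled.

## Nuclei counting

The proliferation readout mirrors the classic ImageJ recipe: threshold an
8-bit single-channel image (default 30–255), label 8-connected components,
optionally split touching nuclei by a watershed on the Euclidean distance
transform, filter particles by area and circularity
(`4π·A/P²`, Crofton perimeter, clamped at 1; pass-all defaults 0–∞ and
0.00–1.00), and convert counts to nuclei/mm² from the pixel size.
Watershed seeds are distance-transform maxima separated by at least
`min_peak_separation_px` (default 4 px).  This separation is a *lower
bound on a credible nucleus radius* rather than the mean radius: with
jittered radii an asymmetric fused pair (say r = 10 px against r = 5 px)
has its second distance peak closer to the first than one mean radius, and
a mean-radius separation silently merges it.  Any component the peak
detector misses keeps a single seed at its distance maximum, so splitting
can never undercount relative to plain connected components.  A reference
tool's exact splitting is not bit-reproducible, so accuracy is assessed
against the generator's placement record, not against any particular GUI
implementation.

Small assay formulas live alongside: relative qPCR expression
`2^−ΔΔCT`, loading-normalised western-blot band intensity relative to a
reference lane, and punctate (proximity-ligation) signals per nucleus.

## Synthetic data: what it emulates and what it does not

Generators are pure functions of parameters and seed; every dataset ships
its ground truth, and recovery tests compare against that record, never
against hard-coded numbers.  Defaults follow the study conditions:
0.4 Hz imaging frames, calibration steps pH 6.0–8.0, electrode calibration
baths pH 7.0/6.4 with a near-Nernstian slope (−1/58 pH/mV), lactate
kinetics with K_m = 5 mM, β = 20 mM/pH, baseline pH 7.2, Gaussian ratio
noise σ = 0.01, pH noise σ = 0.005, Poisson ion counts at 10⁴, nuclei of
radius 8 ± 1 px at 1 µm/px.  Where the study conditions state no value
(noise magnitudes, time constants), defaults were chosen once to be
visibly noisy but recoverable.

The cell model is deliberately coarse: pH responses are piecewise
mono-exponential with a single time constant, transporter electrogenicity,
intracellular diffusion gradients and per-pixel heterogeneity are absent,
and the CO₂ response is anchored to the instantaneous pH at pulse onset.
Passing recovery tests therefore demonstrates that the *estimators* are
unbiased and correctly plumbed under the stated noise, not that real cells
obey these kinetics.  Likewise the nuclei generator's uniform disks are far
cleaner than real Hoechst images; counting accuracy on real data will be
limited by staining heterogeneity, not by the algorithm shown here.

## Numerical choices and problem sizes

Time is stored in seconds; rates convert to per-minute at the reporting
boundary.  Delimited text I/O auto-detects comma/tab, accepts an optional
header, and reports malformed rows by line number.  Trace containers
enforce strictly increasing time and finite values at construction, and
their arrays are immutable.  The recovery suite runs the kinetic grid
(pH amplitude {0.1, 0.3} × τ {30, 60, 120} s × noise {0, 0.005}) with 200
simulated cells per noisy setting at 10 Hz sampling — sizes chosen so the
standard error of each setting's mean is a few percent while the whole
suite stays well under a minute.  Analysis drivers use 24 cells per
condition and 4–6 replicates per assay, comparable to the cell counts of
a typical imaging batch.

## Known limitations

* The max-slope statistic is biased upward on noisy traces (extreme-value
  selection); prefer fixed-window extraction when the onset is known.
* β_i assumes instant CO₂ equilibration and zero pre-pulse bicarbonate;
  cells with residual CO₂/HCO₃⁻ will read high.
* Badger units depend on the uncatalyzed window being genuinely
  enzyme-free; contamination before lysate addition compresses U.
* The watershed splits disks reliably; heavily elongated or clumped (>2)
  nuclei may still merge, which is why acceptance allows ±1 at 30% fusion.
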