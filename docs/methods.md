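# Methods

## The synthetic barn

Each zone is modelled as a single well-mixed compartment (CSTR): with
zone volume `V` (m³), ventilation `Q(t)` (m³ h⁻¹), gas source `S(t)`
(g h⁻¹) and outdoor background `C_out` (g m⁻³),

    V dC/dt = S(t) + Q(t) (C_out − C).

The state variable is mass concentration; sensors see the mixing ratio,
obtained through the ideal-gas conversion at the zone's instantaneous
temperature and the site pressure (101325 Pa by default). Integration
uses the exact exponential step for piecewise-constant coefficients on
a 10 s grid — the grid matches the fastest sensor sampling period, and
the discrete trajectory coincides with the analytic solution of the
linear ODE on every step (tested to 1e-9 relative). Two initial
conditions are supported: `background` (the barn starts clean and fills
over a few time constants `V/Q`) and `steady` (the run starts on the
steady state of the base source), the latter being the regime in which
the tracer balance below is exact.

Why a well-mixed model and not CFD or multiple coupled compartments:
the tracer-gas estimator itself assumes well-mixed air, so this is the
simplest generator under which the estimator's correctness can be
checked *exactly*, by parameter recovery, rather than approximately.
Spatial structure is represented at the between-zone level (zones with
different `S/Q` ratios order their steady-state concentrations
accordingly), not within a zone.

Other channels: outdoor temperature is a sinusoid (mean, amplitude,
peak hour); indoor air sits a constant animal-heat offset above it,
3 °C by default — the typical average excess observed in open dairy
barns. RH is a clipped AR(1) process around its mean (φ = 0.98,
σ = 1%); real humidity co-varies with ventilation and temperature, but
no downstream estimator here depends on RH dynamics, so a stationary
noise model suffices. Illuminance follows a half-sinusoid daylight
curve; sound, PM, VOC and NOx are constant baselines. Management events
(feed delivery, default 07:15 and 16:30 for 60 min, multiplier 2)
scale the gas sources inside their windows.

Everything is reproducible bit-for-bit from (configuration, seed); the
full parameter set is written into the ground-truth object and its JSON
sidecar so estimators can always be scored against truth.

## The virtual node

Sampling follows the firmware schedule: electrochemical gases and sound
every 10 s, temperature/RH/CO2/illuminance every minute, PM and VOC
every 15 min, all folded into 10-minute records carrying avg/min/max.
A 15-minute channel therefore skips every third window; its presence
flag is cleared rather than padded with stale values. Where a
measurement period spans a window boundary, the window that contains
the sample's completion timestamp reports it — one plausible reading of
"most recent completed, not yet reported".

Noise convention: a datasheet accuracy is interpreted as a 2-sigma
half-width, so the sensor adds Gaussian noise with SD = accuracy/2,
with relative accuracies evaluated at the reading and mixed
absolute/relative specs (CO2: ±30 ppm/±3%) resolved as the larger of
the two at the operating point. Readings saturate at the range limits
(e.g. the NDIR CO2 channel never reports below its 400 ppm floor)
because physical sensors clip rather than reject.

The binary packet is 12 header bytes (magic 0xA5, version, node id,
slot, window start, 13-bit presence bitmap in a fixed channel order),
then avg/min/max per present channel as big-endian signed 16-bit
fixed-point (temp/RH/NH3/H2S ×100, sound/PM ×10, others ×1), closed by
CRC-16/CCITT-FALSE. One deliberate limitation: the ×1 illuminance scale
saturates at 32 767 lux inside int16, well below the sensor's 128 klux
ceiling; bright outdoor readings encode as the saturation value. The
codec is the identity on the representable quantized domain (property-
tested on randomized records). Uplink uses 600 one-second slots per
10-minute period, assigned injectively in registration order.

## Gateway semantics

Incoming telemetry is held in a bounded RAM queue while the uplink is
down; overflow spills oldest-first to a persistent flash queue, which
survives power cycles (RAM that was never spilled is lost — matching
the double-buffering design, which persists only under pressure). On
reconnection flash is flushed before RAM. Delivery is exactly-once,
enforced by a (node id, window start) ledger; messages keep their
node-side timestamps, so late delivery never shifts data in time. The
no-loss guarantee — every unique message delivered exactly once in any
receive/outage sequence that eventually reconnects — is a randomized
property test.

Resampling to hourly/daily takes the arithmetic mean of available
records and records coverage; a bin under 50% coverage is reported
missing. The 0.5 threshold is a package choice — it keeps single
dropouts harmless while refusing to report an "hourly mean" built from
one or two packets.

THI uses the NRC/Kelly–Bond form
`THI = (1.8T + 32) − (0.55 − 0.0055·RH)(1.8T − 26)`; the function is a
plain callable so sites preferring another THI variant can swap it.

## Calibration and repeatability

Span calibration fits the two-point line `raw = offset + gain·ppm` and
refuses equal reference concentrations or a non-positive gain (a
falling response is a sensor fault, not a calibration). Zero
calibration stores `offset = raw − reference` with the reference
required to lie inside the CO2 range. The EEPROM is emulated as a
small JSON document per sensor board.

The repeatability report computes, per 10-minute interval and channel,
the mean and sample (n−1) SD of absolute deviations across nodes, then
time-averages those statistics. The reference defaults to the
cross-node mean — the ambient co-location check has no independent
truth — and can be switched to a known applied concentration in bench
mode. Relative errors are computed per interval against that interval's
reference and then averaged (the alternative ordering, relative of the
time-averaged absolutes, gives close but not identical numbers; the
per-interval form weights all conditions equally).

## Welfare analytics

Exceedance flags a device when its period mean strictly exceeds the
limit (equality is not a violation); the time-above-limit fraction uses
the finest resolution supplied. Uniformity across monitoring points is
a one-way comparison on hourly values with Tukey's all-pairs HSD at
α = 0.01 and a Piepho-style insert-and-absorb compact letter display;
the overall heterogeneity statistic is the one-way ANOVA F. A GLM with
some other family could replace this, but on hourly means the normal
one-way model is the transparent default, and its familywise error
calibration is verified by simulation in the test suite. Spatial maps
use inverse-distance weighting with exponent 2 on a 0.5 m grid — exact
at device positions, bounded by the device extremes, and sufficient for
"where is the poorly ventilated corner" questions; kriging is out of
scope.

## Emission estimation

The tracer balance `E_NH3 = P_CO2 · ΔC_NH3 / ΔC_CO2` runs hourly on
cross-device means of the indoor nodes, with ppm converted to g m⁻³ at
each measurement point's own temperature. Herd CO2 production uses the
CIGR dairy form: Φ_tot = 5.6 m^0.75 + 22 Y + 1.6e−5 p³ W per head
(m = body mass kg, default 650; Y = milk yield kg day⁻¹; p = pregnancy
days), linearly corrected by 4 W per hpu per °C below/above 20 °C,
0.185 m³ CO2 h⁻¹ per heat-producing unit (1 hpu = 1000 W), converted to
mass at the barn temperature. Energy intake enters only through the
maintenance and milk-yield terms; no activity correction is applied by
default. Hours with a non-positive indoor–outdoor CO2 difference are
excluded as singular rather than clipped; a day reports only if at
least 12 hours are valid, and the per-animal rate is
24 × daily mean / herd size.

Under the well-mixed generator at steady state with the zone CO2
source matched to the herd model, the estimator returns the true NH3
source to float precision for any ventilation rate — the flow cancels
from the ratio. This identity is the core correctness check; the noise
study then perturbs it with the datasheet sensor accuracies.

## Problem sizes and numerical choices

The recovery and robustness studies use one-day scenarios at the 10 s
grid (8640 steps per zone): 50 randomized noiseless barns for the
tracer identity, 200 noise replicates of the dairy scenario (median
daily estimate within 10% of truth; in practice it lands well under
1%), 500 null replicates for the uniformity calibration and 1000 for
calibration recovery. These sizes give Monte-Carlo errors comfortably
below the quantities being checked while keeping the whole suite at a
few minutes on one CPU. Tie-breaking and degenerate inputs are
resolved explicitly: window means are clamped into [min, max] to
absorb 1-ulp float excursions on constant data, IDW returns the exact
device value at zero distance, and zero-variance inputs to the
correlation are rejected rather than returning NaN.

## What the synthetic data does and does not show

The generator reproduces the statistical structure the analytics are
designed for — diurnal cycles, feeding pulses, spatial S/Q gradients,
sensor noise at datasheet accuracies, outdoor background — but not
drift and cross-sensitivity of electrochemical cells, wind-driven
short-term ventilation fluctuations, within-zone stratification, or
humidity interference. Passing tests therefore demonstrate the
correctness of the pipeline and estimators under their stated
assumptions, not field accuracy of any particular sensor; on a real
barn the tracer method additionally inherits the uncertainty of the
herd CO2 model and of low-cost CO2 sensing. Scenario ventilation rates
and volumes are illustrative, not reconstructions of real farms.
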