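# Methods

`dgsep` models pattern separation in the dentate gyrus (DG) as a
population-of-networks problem: many spiking networks, identical in
architecture and differing only in their neurons' parameters and their
synaptic weights, are generated by unbiased random sampling and kept only
if they satisfy functional validation criteria. This note documents the
models, the measurement conventions, the numerical choices, and — because
several quantitative tables of the biological system are not available —
the calibration decisions behind the package defaults.

## Neuron model

Every neuron (granule cell GC, basket cell BC, mossy cell MC, HIPP cell
HC) is an adaptive exponential integrate-and-fire (aEIF) unit:

    c_m dV/dt   = g_l (E_l − V) + g_l Δ_T exp((V − V_th)/Δ_T) + ΣI_syn − w
    τ_w dw/dt   = α (V − V_th) − w
    at V ≥ V_th: spike; V → V_reset, w → w + b; 5 ms refractory period

with c_m = C_m·A and g_l = A/R_m, so cell geometry enters through the
surface area A. Ten parameters define a cell (C_m, R_m, A, E_l, V_th,
Δ_T, V_reset, τ_w, α, b); the stochastic search samples nine of them and
holds the specific capacitance C_m at its subtype default, since specific
capacitance is the least variable of the ten biophysically.

Internal units are coherent (mV, ms, µF, mS, µA); α (µS), b (nA) and
protocol currents (pA) are converted at the boundary. Integration is
explicit forward Euler at dt = 0.1 ms. The exponential spike-initiation
term is clamped at a configurable argument ceiling (default 20) so a
single step never overflows; the spike test V ≥ V_th happens after the
step. During the refractory window the membrane is held at V_reset while
w continues to evolve and synaptic conductances keep integrating — the
refractory semantics are not dictated by the membrane equations, so this
convention is explicit and configurable in one place (`step_batch`).

Note one consequence of coupling w to (V − V_th) rather than to
(V − E_l): the adaptation current is nonzero at rest, and the resting
potential sits at the coupled fixed point
V_rest = (g_l E_l + α V_th)/(g_l + α) rather than at E_l. The
subthreshold input resistance likewise becomes 1/(g_l + α). The
electrophysiological protocols measure the cell as a black box, so all
validation bounds refer to these observed quantities.

## Electrophysiological protocols

Six measurements characterize a model: membrane time constant τ_m
(single-exponential fit to the 20 pA / 1500 ms charging curve), sag ratio
(steady-state over peak deflection at −50 pA / 1 s), input resistance
R_in (slope of steady-state deflection vs current over −40..40 pA step 10;
−20..20 step 5 for HC, which fire above 20 pA), firing frequencies f50
and f150 (spike counts for 1 s pulses), and spike-frequency adaptation
SFA (first/last inter-spike interval at 150 pA, defined only with ≥ 3
spikes). Conventions the protocols fix where the measurement definition
is silent: a 500 ms settling segment precedes every pulse; baselines are
means over the 100 ms before onset; steady states are means over the last
10 % of the pulse; the exponential fit is nonlinear least squares seeded
from a log-linear estimate over the full pulse window; a model that
spikes during a subthreshold protocol gets an undefined (NaN)
measurement, and an undefined measurement fails validation — it is never
imputed. Protocols are vectorized across models, so measuring a searched
population of thousands costs a handful of batch simulations.

## Stochastic searches

The cellular-scale search samples each parameter independently and
uniformly within subtype-specific ranges and declares a model valid only
if all six measurements fall in the subtype's admissible range. Each
subtype search runs on an independent stream derived from a master seed.
Full-scale candidate counts (100 000 / 60 000 / 10 000 / 20 000 for
GC/BC/MC/HC) are configuration defaults; the desk-scale profile uses
1200/400/400/400, which yields hundreds of valid models per subtype in
seconds.

The network-scale search holds one heterogeneous neuron assignment, one
adjacency realization, and one 11-pattern input set fixed, and samples
only the eight projection weights from uniform ranges. A candidate is
accepted when all eight separation measurements (four per correlation
metric, below) satisfy the validation bounds.

## Network architecture

Populations default to 3600 GC, 500 BC, 180 MC, 50 HC with 700
perforant-path (PP) afferents; the desk-scale profile is 240/40/16/8 with
200 afferents (same proportions). Exactly eight projections exist:
PP→GC, PP→HC, GC→BC, GC→MC, MC→GC, MC→BC (excitatory, colocalized
AMPA+NMDA), BC→GC and HC→GC (GABA_A). Weights are per-projection scalars
— the search space is eight-dimensional — and NMDA peak conductance is a
fixed per-projection ratio of the AMPA peak conductance.

Two wiring modes are implemented. `bernoulli` realizes every potential
edge independently with the projection's connection probability.
`fixed_in_degree` (the experiment default) gives every postsynaptic cell
exactly round(p·n_pre) distinct presynaptic partners, the
fixed-divergence convention of anatomically grounded DG circuit models.
The distinction matters scientifically: under Bernoulli wiring the
binomial spread of excitatory and inhibitory in-degrees is a quenched
per-cell bias that dominates granule-cell mean firing rates. At reduced
network scale this pins the across-pattern correlation of GC rate vectors
near 0.3–0.9 even for completely unrelated inputs, which makes effective
separation under the average-rate metric unreachable regardless of the
weight vector. Fixed in-degree removes that bias while leaving all other
heterogeneity (cell parameters, partner identity, input realizations)
intact.

## Synapse model

Conductances follow the difference of exponentials
u(t) = exp(−t/τ_decay) − exp(−t/τ_rise), normalized by its analytic
maximum so the weight ḡ is the true peak conductance. Each
projection-receptor pair keeps rise/decay state variables per
postsynaptic cell, advanced by exact per-step decay factors; arrivals
increment both exponentials after the projection delay (rounded to the
nearest step; delays of 1–3 ms). NMDA receptors are additionally scaled
by the magnesium-block sigmoid s(V) = 1/(1 + η[Mg]_o exp(−γV)) with
η = 0.28 mM⁻¹, [Mg]_o = 1 mM, γ = 0.04 mV⁻¹ (s(0 mV) = 1/1.28 ≈ 0.781).
Synaptic drive enters the membrane equation as g·(E_syn − V) — an
excitatory conductance (E = 0 mV) depolarizes a cell below 0 mV, an
inhibitory one (E = −90 mV) hyperpolarizes above −90 mV.

Optional additive zero-mean Gaussian noise is applied to every neuron's
summed synaptic current independently at each step. The noise level σ is
dimensionless (1/3/5 for low/medium/high); the native scale is
σ × noise_unit with noise_unit defaulting to 20 pA. Weight jitter draws
one zero-mean Gaussian per projection with SD σ × jitter_unit
(jitter_unit = 1e-6 mS = 1 nS); jittered weights are floored at zero
because a conductance cannot be negative. Both unit factors are
configuration entries — the dimensionless levels have no published native
scale, so the defaults were chosen to make the high level a substantial
but not catastrophic perturbation of the default weight magnitudes
(4×10⁻⁷–3×10⁻⁵ mS).

## Input patterns

A pattern is 700 independent spike trains, 2 s long. Per-train rates are
drawn from a Poisson distribution with mean 8 Hz (so the across-train
firing-rate histogram is Poisson-shaped); each train is then a
homogeneous Poisson process at its rate, built by accumulating
exponential inter-spike intervals (population mean ISI 125 ms). A
constant-rate variant (all trains exactly 8 Hz, pooled ISIs exactly
exponential) and an exponential-rate variant exist for the
metric-invariance study. The across-train rate heterogeneity is not
cosmetic: a granule cell's mean drive is the sum of its sampled trains'
rates, so replacing trains changes mean drive — that is the channel
through which the average-rate similarity of the *output* can fall with
the morph parameter.

Morphing: two independent base patterns P0, P1 (accepted only if their
rate-vector correlation satisfies |r| < 0.1, else regenerated) are bridged
by replacing round(β·700) trains of P0 with their P1 counterparts, for
β = 0, 0.1, …, 1 (11 patterns). Replacement is nested — one random
permutation, P_β takes its first round(β·n) entries — so replaced sets
grow monotonically and the morph is progressive; independent per-β
selection is available (`nested=False`). Rounding is half away from zero.

## Similarity metrics

Six metrics compare per-neuron firing rates over the analysis window
(500–2000 ms): Hamming distance, normalized Euclidean distance, cosine
similarity, plug-in mutual information, the Pearson correlation r of
average-rate vectors, and the instantaneous-rate correlation R. For
HD/nED the rates are first normalized by the maximum over the two
compared patterns (the normalizer is a convention; correlations are
scale-free). MI uses 10 equal-width bins over the pooled range. For R,
each train is smoothed with a Gaussian kernel of SD 1/(10f) seconds (f
the train's own rate; silent trains give the zero series, and Pearson
with a constant series is defined as 0), the N×N within-pattern
correlation matrices are built, and R is the Pearson correlation of their
upper triangles (diagonal excluded, since it is identically 1). Smoothed
series are sampled at 2 ms (2.5 ms in the invariance harness) with the
kernel truncated at ±4 SD — at the default rates the kernel SD is ≥ 4 ms,
so this sampling is comfortably fine.

The invariance harness regenerates 10 independent P0–P1 pairs per setting
of one factor — population size (1000/2000/3000 trains), mean rate
(5/15/25 Hz), or rate-distribution form (Poisson vs exponential) — and
averages metric-vs-β curves across sets. The correlation metrics' mean
curves coincide across settings to within sampling tolerance (≲ 0.05 at
10 sets) while the distance metrics shift systematically with rate and
size; this is the quantitative basis for using r and R as the
input/output similarity measures.

## Separation quantification

For each network, output similarity S_out (GC responses to P0 vs P_β) is
plotted against input similarity S_in for the 11 morph levels, separately
for r and R. The points are rotated clockwise by 45° —
x′ = (S_in+S_out)/√2, y′ = (S_out−S_in)/√2 — so separation is y′ < 0. A
cubic polynomial p(x′) is least-squares fitted (all 11 points, including
the β = 0 self-comparison anchor at (√2, 0); duplicated abscissae fall
back to a lower degree). Four measurements follow, over the observed x′
range only (extrapolating a cubic beyond data is meaningless): A_PS and
A_PC are the areas under the negative- and positive-rectified polynomial,
computed by analytic integration between the real roots (no quadrature);
PS_max is the peak of −p at the endpoints and interior critical points;
T_PCPS is the smallest x′ where p crosses from ≥ 0 to < 0 (range start if
p is negative there, range end if it never is — the crossing is
specifically the completion→separation direction, the most ambiguous of
the four definitions and therefore isolated in one code path). A network
is accepted only if A_PS > 0.15, A_PC < 0.02, T_PCPS < 0.25 and
PS_max > 0.2 hold for **both** metrics (a strict 8-way conjunction; an
undefined metric — eg a silent GC population — fails). Root-finding uses
the cubic's closed form via the companion matrix with a |p| < 1e−12 zero
band.

## Calibrated defaults

The biological system's quantitative tables (per-subtype parameter
ranges and measurement bounds, connection probabilities, kinetics,
delays, NMDA ratios, weight ranges) are not published with the study
design this package implements; they ship as editable configuration with
implementer-chosen defaults. The defaults were hand-calibrated once so
that (a) each subtype's base model reproduces qualitatively correct DG
electrophysiology — sparse high-resistance adapting GCs, fast
low-adaptation BCs, adapting MCs, low-rheobase HCs recruited directly by
the perforant path — and (b) a pattern-separating weight configuration
exists at desk scale, around which the search ranges are centred. The
load-bearing choices, and why:

* **GC subthreshold adaptation α = 3 nS** (comparable to g_l ≈ 4 nS) with
  τ_w = 150 ms: strong slow negative feedback subtracts each cell's own
  mean drive, making granule cells fluctuation (coincidence) detectors
  whose firing depends on which afferents they sample rather than on
  their tonic excitability. This also produces the GC sag (≈ 0.7) and
  adaptation signatures the validation bounds encode.
* **Sparse afferent convergence** (PP→GC p = 0.02, strong unitary
  conductances): with few inputs per GC, replacing a β fraction of trains
  changes a cell's drive composition strongly, maximizing the
  input-specificity of the output code.
* **Dense inhibitory convergence** (BC→GC, HC→GC p = 0.4): every GC sees
  a comparable inhibitory background, so inhibition acts as a
  population-level threshold rather than a per-cell quenched bias.
* **Tight GC signature bounds** (R_in 130–190 MΩ, f150 5–18 Hz, sag
  0.5–0.8): heterogeneity within these bounds is what the study design
  means by "validated heterogeneous" — models remain visibly diverse in
  parameters while equivalent in function.
* **Fixed in-degree wiring** for the experiment profile (above).

With these defaults the desk-scale searches accept roughly a third to
three quarters of weight candidates depending on the seed — deliberately
far denser than a full-scale search over wide, uncentred ranges, where
acceptance is a fraction of a percent; the package's reduced profile is
built to *study* accepted networks, not to reproduce the rarity of
acceptance, and the wide-range full-scale search remains available
through configuration.

## Problem sizes and determinism

The desk-scale profile (240/40/16/8 neurons, 200 afferents, 1200/400/400/
400 cell candidates, 60 weight candidates) runs the complete pipeline —
four cell searches, network assembly, 11-pattern simulations for every
candidate, both metrics, quantification and validation — in under ten
minutes on one core; the batched engine integrates all 11 patterns of a
candidate simultaneously. Every stage draws its seed from a single master
stream, and with noise disabled a simulation is a pure function of
(network, patterns, engine settings): identical seeds reproduce every
number exactly, which the test suite asserts.

## Known limitations

* The aEIF abstraction has no dendrites, ion-channel repertoire,
  short-term plasticity, or gap junctions; interneuron subtypes differ
  only through their parameter distributions and wiring.
* Synthetic Poisson afferents lack the temporal and spatial structure of
  real entorhinal input; passing the invariance and separation tests
  shows the metrics and the circuit mechanism behave as designed, not
  that the biological DG is quantitatively captured.
* All bounds, probabilities and kinetics are placeholder calibrations
  (above); conclusions that depend on their precise values — yields,
  acceptance fractions, absolute sparsity levels — are not comparable
  across configurations.
* The average-rate metric r is noisy at reduced scale (few hundred GCs,
  sparse firing), which is visible as scatter in S_out-vs-S_in curves;
  the instantaneous-rate metric R is far more stable.
* Percent-change summaries of the perturbation studies are descriptive;
  no inferential statistics are computed.
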