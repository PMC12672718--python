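# Methods

## The model

Every neuron of the circuit is an electrically compact, single-compartment,
conductance-based graded element.  Its membrane potential `V_i` obeys a
five-current balance: capacitive, excitatory synaptic, inhibitory synaptic,
ohmic leak, and an optional hyperpolarization-activated (H) current,

    -C_m dV_i/dt = (V_i - E_exc) g_exc,i + (V_i - E_inh) g_inh,i
                   + (V_i - E_leak,i) g_leak + (V_i - E_rev) g_h,i - I_i

with injected stimulus current `I_i`.  Synaptic conductances are built from
the connectome.  The signed synapse-count matrix over cell types (sign =
presynaptic transmitter, entry `(i, j)` = synapses from presynaptic `j` onto
postsynaptic `i`) is split into non-negative excitatory and inhibitory
matrices and tiled across a linear array of columns: same-column blocks carry
the intra-columnar matrix, adjacent-column blocks the inter-columnar matrix,
applied identically to the left and right neighbor.  Boundary columns are
simply truncated (no wraparound); only the central column is read out
downstream, which is why truncation is acceptable.  Each presynaptic neuron's
output is its voltage rectified at a fixed threshold times its type's output
gain; each postsynaptic neuron scales its weighted input sum by its type's
input gain:

    g_exc,i = inp_gain(i) * sum_j M_exc[i,j] * out_gain(j) * max(V_j - trld, 0)

and likewise for `g_inh`.  Because the two gains apply uniformly to all of a
neuron's synapses, the relative strengths fixed by the synapse counts are
preserved; the gains are the model's only per-type free parameters.

The H-conductance of gated types relaxes toward a logistic steady state

    g_inf(V) = g_max / (1 + exp((V_mid - V) * slope))

with a bell-shaped voltage-dependent time constant

    tau(V) = 1.5 / (e^x + e^-x) + 0.1,   x = 0.1 (tau_midV - V)

which peaks at 0.85 at `V = tau_midV` and floors at 0.1.  A negative `slope`
makes the conductance open under hyperpolarization; with a reversal potential
above the hyperpolarized operating range this produces the classic sag during
a sustained hyperpolarizing input and a rebound depolarization at release.

### Units

Voltages in mV, conductances in nS, capacitance in pF, currents in pA; the
membrane equation then integrates naturally in milliseconds (pF/nS = ms).
The gate time-constant formula is dimensionless as written; this package
interprets its output as **seconds** and converts (x1000) for the membrane
loop.  That choice puts the gate kinetics at 100-850 ms, the timescale of the
slow sag transients the gate exists to produce; interpreting the formula in
milliseconds would make the gate as fast as a single integration step and
functionally inert.

### Reference constants

| quantity | value | meaning |
|---|---|---|
| `C_m` | 40 pF | shared membrane capacitance |
| `g_leak` | 1 nS | shared leak conductance (tau_m = 40 ms isolated) |
| `E_exc` / `E_inh` | +10 / -70 mV | synaptic reversal potentials |
| `trld` | -50 mV | presynaptic rectification threshold |
| `E_leak` | -50 mV (-20 mV for the first three lamina types) | per-type leak reversal |
| `E_rev` (gate) | -30 mV, configurable | gate reversal; any value above the hyperpolarized lamina range yields the depolarizing sag current; not optimized |
| `dt` | 10 ms | protocol integration step |

All neurons share `C_m` and `g_leak`: isolated from the network they have
identical passive membrane time constants, so every difference in response
dynamics must come from connectivity or from the gate.

## Numerical scheme

Explicit (forward) Euler for both the membrane and the gate at the protocol's
10 ms step (`dt/tau_m` = 0.25, stable for the passive core; the gate's
time-constant floor of 100 ms keeps `dt/tau <= 0.1`).  Update order per step:
synaptic conductances from `V(t)`, gate update from `V(t)`, membrane update
using the fresh gate value (frozen coefficients; no implicit coupling).  An
exponential-Euler option exists for stiff synaptic regimes and convergence
tests; it settles to the same steady states and is unconditionally stable,
but the fitting path uses plain Euler.  Initial conditions are `V(0)` =
per-type `E_leak` and `g_h(0)` = `g_inf(V(0))`; the 0.5 s pre-stimulus window
of the 2 s trace serves as settling time, so no separate equilibration run is
made.  Strongly over-coupled parameter draws can make explicit Euler diverge;
divergence is detected by a finiteness check, reported with the step index,
and treated by the fitter as a failed restart (never silently retried).

The rectifier uses exact `max(., 0)` with subgradient 0 at the kink, so
gradients through the network are well defined everywhere.

## Stimulation protocol and read-out

A constant depolarizing current step (default 20 pA - the amplitude trades
off against the gains and is absorbed by fitting) is injected into all
photoreceptor-flagged types of the central column from t = 0.5 s through the
end of the 2 s window (no off-transient within the window; pulse protocols
are available through `t_off`).  Spatial receptive fields are read from the
*spread* of activity: type `n` at position offset `d` is the trace of `n`'s
neuron in column `center + d`.  This is the standard shortcut for a
(locally) shift-invariant network - it replaces one simulation per stimulus
position by a single simulation.  With truncated boundary columns the
equivalence with explicit stimulus displacement is not exact: the two
measurements differ by activity paths that would cross the array boundary,
whose magnitude scales as a high power of the inter-columnar coupling.  The
test suite checks the equivalence exhaustively over all offsets on a weakly
inter-coupled synthetic network at a 1% (of peak response) tolerance.

Voltage traces are passed through a first-order low-pass with a 50 ms time
constant - a proxy for calcium-indicator dynamics, since the target data come
from calcium imaging - then referenced to their value at the onset sample,
with pre-onset samples hard-zeroed.  Filtering precedes baselining.  The
filter is discretized exactly for zero-order-hold input
(`a = 1 - exp(-dt/tau)`), so a constant trace passes through unchanged and
the step response crosses `1 - 1/e` exactly at `tau`.

## Target preparation

Measured impulse responses are integrated over time into step responses
(running sum x dt), then scaled by **one global factor** so the maximum
magnitude across all types equals 20 mV.  The global (rather than per-type)
reading preserves the relative amplitudes between cell types, which the cost
function must see; a per-type option exists but is off by default.  For
tonically active types (reference: the first two lamina monopolar cells,
which hyperpolarize to light on top of a standing depolarization) a DC offset
of 40% of that type's peak post-onset magnitude is added to the post-onset
samples.  The order integrate -> normalize -> add-DC is enforced; a prepared
target set refuses re-normalization because it would silently break the
fraction-of-peak semantics.

## Cost and optimization

    cost(z) = sum_{n,x,t} (model - data)^2 / sum_{n,x,t} data^2

over observed types x positions x time - the deviation as a fraction of the
data power, so 0 is perfect and 1 is the null model (identically zero
responses).  Free parameters: 2 gains per type (130 for 65 types), plus, with
the gate enabled, one `g_max` per gated type and shared `V_mid`, `slope`,
`tau_midV` (138 for 5 gated types).  Gains and `g_max` are optimized through
a softplus reparameterization, making non-negativity structural (a negative
gain would silently violate the transmitter-sign split of the connectome).
The gate voltages are unconstrained.

Gradients are exact reverse-mode derivatives: the cost adjoint is pulled back
through baselining and the low-pass (both linear, with hand-derived
adjoints), then through the unrolled Euler recursion (backpropagation through
time over the full 200-step trace), accumulating per-type gradients.  The
test suite verifies every coordinate against central finite differences to
1e-3 relative error.  The optimizer is Adam (beta1 = 0.9, beta2 = 0.999, eps
= 1e-8, moments carried across rounds) with the reference schedule of three
consecutive rounds of 10,000 steps at learning rates 0.1 / 0.01 / 0.001,
repeated from 20 independent random restarts; restart `r` seeds its generator
with `base_seed + r`, making every run bit-reproducible.  The best model is
the minimum-final-cost restart; non-finite restarts are flagged failed and
excluded from ranking.

Initialization (the choice is open; only "random parameter set" is
prescribed): gains are drawn log-uniformly from a connectivity-derived range
centered on `gain0 = 1/sqrt(W * 30 mV)` (W = mean total synaptic weight per
neuron), which puts typical synaptic conductance totals on the order of the
leak conductance - inside explicit Euler's stability region and on the
physically sensible operating scale.  Gate voltages draw uniformly from
physiological windows (`V_mid`, `tau_midV` in [-80, -20] mV, `slope` in
[-1, 1] /mV) and `g_max` log-uniformly from [0.5, 5] nS.

Ablation (`ablate_gate`) zeroes every `g_max` of an optimized model, leaving
all other parameters untouched - the in-silico analog of blocking the
current after the network has learned to rely on it.

## Ensemble evaluation

The `k` best of the restarts (reference: 10 of 20) are compared by pairwise
Pearson correlation of their constrained (physical-scale) parameter vectors -
correlations near 1 mean independent runs converged on similar circuits - and
summarized by per-parameter mean and population variance (divide by `k`;
standard deviation available via flag).  The with/without-gate report records
best and median costs per condition, their ratio, and the ablated cost.

## Synthetic study conditions

The generator stands in for the real inputs (an EM-derived synapse-count
matrix split into intra- and inter-columnar parts, and calcium-imaging
receptive fields of 13 of the 65 types).  It emulates their structural
properties: integer synapse counts at configurable density (reference
defaults: 65 types, 15% intra / 5% inter density, counts up to 50), one sign
per presynaptic type (Dale consistency by construction), photoreceptors
negative onto their targets (histamine-like, so light hyperpolarizes the
first-order interneurons), lamina-like types with depolarized leak reversal
(-20 mV for the first three) that keeps them tonically active, and gate
parameters with negative slope so the ground truth genuinely produces sag and
rebound.  Connectivity guarantees (every lamina type hears a photoreceptor;
every interneuron has an input path) ensure the stimulus drives the whole
circuit; they are skipped for deliberately empty zero-density matrices.

Targets are generated by running the measurement pipeline on the ground
truth, restricting to an observed subset (default: all non-photoreceptor
types; the reference regime observes 13 of 65), and optionally adding
Gaussian noise to post-onset samples.  Under additive noise the expected
self-fit cost is `N*X*(T-onset)*sd^2 / power` (pre-onset samples carry no
noise by the tensor convention), which the tests verify by Monte Carlo and
use as an overfitting sanity bound.

What the generator does **not** emulate: realistic degree distributions or
motif statistics of the fly connectome, hexagonal two-dimensional geometry,
gap junctions, and the specific identities of the 65 cell types.  Passing
the recovery tests therefore shows the pipeline is correct and the estimator
consistent under its own assumptions - not that the model family captures
real optic-lobe data.

### Identifiability

Input and output gains are only jointly constrained (an input/output product
degeneracy on unobserved paths), so recovery is asserted on **responses**,
not raw gain vectors: the test-suite criterion is that the best fit's
response tensor disagrees with the ground-truth tensor by less than 5% in
normalized power (the same functional as the cost) on the observed types.
Unobserved types are deliberately left unconstrained - that is the partial
observability the reference regime lives with.

### Problem sizes used by tests and the acceptance script

Structural checks run at reference scale (65 types x 5 columns).  Fitting
checks run on an 8-type, 3-column fixture (35% intra / 15% inter density -
small matrices need higher density to stay connected) with a reduced budget
of 3 rounds x 1000 steps (600 for the gated ablation fixture) and 5 (or 3)
restarts, sizes at which the full multi-restart fit completes in a couple of
minutes on one CPU while still recovering the ground truth to cost below
1e-4 and showing a severalfold to orders-of-magnitude cost increase under
ablation (the margin varies with the random fixture).

## Known limitations

- Explicit Euler at 10 ms is first-order; strongly coupled fits can ring.
  The exponential-Euler integrator is provided but is not the fitting path.
- No synaptic depression, receptor desensitization, multi-compartment
  morphology, spiking, or inactivating (A-type) potassium currents; the
  generic gate supports a non-inactivating K-current shape (positive slope,
  hyperpolarized reversal) but no reference parameters are shipped for it.
- Gap-junction coupling (relevant to the strong lamina L1/L2 electrical
  coupling) is not modeled as a distinct mechanism.
- The cost weights every observed sample equally; types with small responses
  contribute little and can be under-fit.
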