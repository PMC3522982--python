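# Methods

## Model and assumptions

The package implements a golden-rule (non-adiabatic) description of electron
transfer between two localized, discrete-level sites D and A inside an
olfactory receptor, coupled weakly to one dominant odorant vibrational mode
and to a bath of environment modes summarized by a single reorganization
energy λ. The working assumptions are:

- **Non-adiabatic transfer.** The electronic matrix element |t| is small
  (meV scale), so perturbation theory applies and the rate is proportional
  to |t|². Consequences used throughout: rates scale exactly as |t|², and
  channel *ratios* are independent of |t|.
- **One dominant odorant mode.** The odorant couples through a single
  high-frequency mode ħω₀ with Huang–Rhys factor S. At physiological
  temperature ħω₀ ≫ k_BT (occupation e^(−ħω₀/k_BT) ~ 6·10⁻⁴ for 200 meV),
  so the mode starts in its ground state and the low-temperature
  Franck–Condon weights σ_n = e^(−S)Sⁿ/n! (a Poisson distribution in n)
  apply. These weights are not uniquely dictated by the rate expression
  alone; they are the standard weak-coupling form, and with the default
  parameter set they reproduce the reference channel times (87 ns /
  0.154 ns), which is the package's internal consistency anchor.
- **Classical Gaussian environment.** The environment enters through the
  Marcus activation factor (4πk_BTλ)^(−1/2) exp(−(ε_n−λ)²/4k_BTλ), valid
  when the environment modes are soft (ħω_env ≪ k_BT) and weakly coupled.
- **Channel energies.** ε_n = Δε − n·ħω₀ with Δε the donor–acceptor gap.
  The default receptor is *tuned*: Δε = ħω₀, so ε_1 = 0 (activationless
  inelastic channel) and ε_0 = ħω₀. Detuned receptors are expressed through
  `da_gap`.

## Parameters, units, defaults

| Parameter | Meaning | Default | Why |
|---|---|---|---|
| ħω₀ | odorant vibrational quantum | 200 meV | representative quantum for the high-frequency modes relevant to discrimination |
| S | odorant Huang–Rhys factor | 0.1 | middle of the detectable range 0.01–0.3; below it inelastic events are too rare, above it multiphonon processes blur discrimination |
| λ | environment reorganization energy | 30 meV | a dry hydrophobic pocket; safely below the ~62 meV crossover |
| \|t\| | electronic matrix element | 1 meV | order-of-magnitude estimate for weakly overlapping sites; comparable values are measured in bacterial electron-transfer systems |
| k_BT | thermal energy | 27 meV | body temperature, kept at the conventional rounded value so that the default operating point reproduces the reference times exactly; k_B·300 K = 25.852 meV is used where a 300 K laboratory value is meant |
| Δε | donor–acceptor gap | = ħω₀ | the tuned receptor |

Energies are carried as `EnergyQuantity` values with explicit units (eV,
meV, cm⁻¹, J); conversions use CODATA 2018 (1 eV = 8065.543937 cm⁻¹,
ħ = 6.582119569·10⁻¹⁶ eV·s, e²/4πε₀ = 14.39964 eV·Å). One inherited
inconsistency is documented rather than patched: the commonly quoted pairing
"0.36 eV ≈ 2911.3 cm⁻¹" for C–H stretches implies a nonstandard conversion
factor; with the CODATA factor 0.36 eV is 2903.6 cm⁻¹. The package always
uses the standard factor.

Frequencies in the discrimination layer are stored in cm⁻¹ (spectroscopy
convention); the hydrogen-stretch oscillator mass convention is M = 1 amu
(only the proton moves), with a reduced-mass option for heavier partners.

## Tunnelling-rate layer

`transfer_rate` evaluates the channel rate directly in eV/seconds units.
Numerical choices:

- Channel weights are computed with `scipy.stats.poisson.pmf`; the default
  truncation n_max = 10 keeps the normalization error below 10⁻¹⁰ for
  S ≤ 0.3.
- `crossover_lambda` uses the closed form λ* = ħω₀²/(2ħω₀ − 4k_BT ln S),
  obtained by equating the n = 0 and n = 1 rates for the tuned receptor. It
  is defined for any S > 0 whose root lies in (0, ħω₀); outside that
  interval (very strong coupling) a `ValueError` states that no crossover
  exists below the quantum. An independent bisection solver
  (`crossover_lambda_bisect`, Brent's method on the log-rate difference,
  default bracket 1 meV to ħω₀ − 1 μeV, xtol 10⁻¹²) is provided and used in
  tests as the oracle; closed form and bisection agree to better than
  10⁻⁹ eV.
- The outer-shell (dielectric continuum) reorganization energy implements
  both the `as_printed` (+1/r₁₂) and `standard_marcus` (−1/r₁₂) sign
  conventions for the two-sphere cross term; the printed form is the
  default for fidelity to the source expression, and the conventional
  Marcus form is one flag away. Both vanish identically when
  D_op = D_S.

## Kinetics layer

The two race models assume *memoryless* competing processes: the source
picture specifies only constant per-unit-time probabilities, and the
exponential distribution is the unique memoryless realization, so holding
times are exponential with means τ_M, τ_W, τ_R, τ_D.

- Frustration model: P(influx | docking) = τ_R/(τ_R + τ_X); right:wrong
  success ratio (τ_R + τ_W)/(τ_R + τ_M).
- Delay model: τ′ = τ_D(1 + τ_X/τ_R); separation (τ_W − τ_M)·τ_D/τ_R.

Defaults: τ_M = 0.1542 ns and τ_W = 87.35 ns are the default-parameter
channel times; τ_R and τ_D default to 31.6 μs, the geometric midpoint of the
1 μs – 1 ms range characteristic of the slow charge-transport steps of the
receptor cycle, and are expected to be overridden per scenario; the neural
integration window defaults to 1 ms. A scenario with τ_M > τ_W is accepted
with a warning (it is physically odd, not invalid).

The simulator (`simulate_receptor_cycle`) draws all randomness from
`numpy.random.default_rng(seed)`; the seed is a required argument and
identical seeds give identical traces. `single_shot` mode (default) allows
at most one influx per docking, so the influx fraction is a binomial
estimator of the analytic success probability — the suite checks agreement
within 3σ at n = 10⁵. `multi_shot` mode lets a docked odorant fire
repeatedly, each repeat gated by an exponential donor-replenishment wait,
until the window closes or the integration window ends. Whether a real
receptor can signal more than once per millisecond is an open question;
both modes are provided without endorsing either, and `single_shot` is the
default because it is the more conservative reading.

## Discrimination layer

A receptor detects a mode iff |ν − δ| ≤ w and S_min ≤ S ≤ S_max, with both
boundaries inclusive (a mode exactly at the window edge counts as detected —
the tie-break is chosen so that the hydrogen-sulphide/decaborane pair, whose
key stretches differ by ~25 cm⁻¹, lands on the "both smell sulphurous" side
with the default window). Defaults: w = 25 cm⁻¹ (differences below ~25 cm⁻¹
are unlikely to be resolved), coupling range 0.01–0.3, with a stricter
0.05–0.3 preset (`USEFUL_COUPLING_RANGE`).

Activation here is deliberately binary; graded efficacy can be obtained by
composing `receptor_activation` with `transfer_rate` on the matching modes,
but is not baked in, keeping the binary-vs-graded question open as
configuration. Antagonism (occupancy without activation) is noted but not
modelled. Activation depends only on the (frequency, S) multiset — mode
order and labels never matter — so mirror-image molecules are
indistinguishable in this layer by construction; differentiating enantiomers
requires chirality-sensitive S or |t| inputs, which are the caller's
responsibility.

Isotope substitution multiplies flagged mode frequencies by the model ratio
(1/√2 for proton-only H→D). The ~800 cm⁻¹ shift often quoted for C–H/C–D
corresponds to a ≈2730 cm⁻¹ base mode; the package treats the *factor*, not
the absolute shift, as the ground truth, so a 3050 cm⁻¹ stretch shifts by
~893 cm⁻¹.

## Synthetic spectra

`generate_synthetic_spectrum` emulates a small organic odorant's mode table:
frequencies uniform over a union of bands (default a 500–1800 cm⁻¹
fingerprint region and a 2400–3200 cm⁻¹ stretch region, bands weighted by
width so the union is sampled uniformly), couplings uniform over the
detectable range 0.01–0.3, and a Bernoulli hydrogen flag (default 0.5). It
does **not** emulate: realistic mode densities or intensity patterns,
correlations between frequency and coupling, anharmonicity, or
receptor-induced mode shifts. Tests passing on these fixtures therefore
demonstrate the *logic* of the discrimination layer (window arithmetic,
combinatorial-code comparisons, isotope bookkeeping), not agreement with any
measured spectrum; quantitative use requires mode tables computed upstream
(e.g. by DFT) and supplied as TSV.

## Degenerate inputs and edge cases

- k_BT = 0 in `thermal_occupation` returns 0 exactly (documented limit);
  `rms_displacement` at T = 0 returns the zero-point amplitude (coth → 1).
- Empty inner-shell mode lists give λ_i = 0; empty spectra never activate;
  an empty receptor panel yields an empty activation row and "not
  discriminated".
- Zero two-phonon coupling makes the multiphonon suppression ratio
  undefined and raises, rather than returning infinity.
- Header-only spectrum files parse to an empty spectrum with a warning;
  malformed rows are reported with their line numbers.

## Problem sizes

All closed-form checks are instantaneous. The stochastic checks use 10⁵
dockings per scenario (binomial standard error ≈ 0.0016 at p ≈ 0.5, small
enough to resolve 3σ departures from the analytic race probability), and the
whole suite runs in a few seconds on one CPU.

## Known limitations

- σ_n uses the strict low-temperature Franck–Condon form; thermally excited
  initial vibrational states (relevant only for ħω₀ ≲ k_BT) are not
  included.
- |t| is a free parameter: no wavefunction-overlap estimate is computed
  (the single-orbital estimate t ≈ υ²/(ε_M − ε_A) is discussed here only as
  context).
- The environment is a single effective λ; structured environments
  (multiple outer-sphere shells, frequency-resolved baths) are out of
  scope.
- The kinetics layer stops at the receptor: no glomerular or neural
  integration model beyond a counting window.
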