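# Methods

This document records the mathematical model, the simulation algorithms, the
estimator conventions, the default parameter choices and their rationale, and
the known numerical limitations of `ratespec`.

## 1. Model

### 1.1 Product-number vs. reaction-rate spectra

The object of study is a product species `z` created by an arbitrary upstream
mechanism and degraded in a first-order step, `z -> 0` at rate `gamma`.  For
any stationary creation process whose instantaneous rate `R(t)` does not
depend on `z` itself, the two-sided power spectrum of the molecule number
separates exactly:

```
S_z(omega) = [ 2<R> + S_R(omega) ] / (omega^2 + gamma^2)
```

`S_z` (the FSPN) is the Fourier transform of the stationary number
autocovariance `<dz(t) dz(0)>`; `S_R` (the FSRR) is the same transform of the
rate fluctuations `<dR(t) dR(0)>`.  The decomposition holds because creation
shot noise (the `2<R>` term) and rate fluctuations are uncorrelated, and the
first-order degradation acts as the transfer function `1/(omega^2 + gamma^2)`
on both.  Inverting it,

```
S_R(omega) = (omega^2 + gamma^2) S_z(omega) - 2<R>
```

extracts the mechanism fingerprint from a number trace.  `fspn_from_fsrr`
and `extract_fsrr` implement the two directions; `lorentzian_background` is
the Poisson floor `S_z0 = 2<R>/(omega^2 + gamma^2)`.

### 1.2 Renewal creation

When creation events renew independently with reaction-time density
`psi(t)`, the FSRR has the closed form

```
S_R(omega) = 2 <R> Re[ psi~(omega) / (1 - psi~(omega)) ],
psi~(omega) = Integral_0^inf psi(t) e^{-i omega t} dt,   <R> = 1/<t>.
```

`renewal_fsrr` evaluates this for any `ReactionTimeModel`:

* `SingleExponential(k)` — `psi~ = k/(k + i omega)`, `S_R = 0` identically
  (the Poisson null).
* `MultiStep([k_1..k_l])` — a chain of sequential exponential steps
  (Erlang when rates are equal); sub-Poisson, `S_R < 0` at low frequency,
  with resonances near multiples of `2 pi / <t>`.  For the equal-rate
  two-step chain the expression reduces symbolically to
  `S_R = -2<R> k^2 / (omega^2 + 4 k^2)`.
* `MultiChannel(p, models)` — a probabilistic mixture of channels
  (e.g. fast/slow pathways); super-Poisson, positive monotone FSRR.
* `GammaDist(mean, cv2)` — Gamma-distributed reaction times,
  `psi~ = (1 + i omega b)^{-a}`.
* `EnzymeTurnover(k1S, es_lifetime, p2)` — substrate binding at
  pseudo-first-order rate `k1S`, complex lifetime of arbitrary
  distribution, catalytic branching probability `p2`; the renewal
  density follows from the branching geometric series.  For `n`
  independent copies of the machine, `multi_enzyme_fsrr` applies the
  superposition result `S_R^{(n)} = n S_R^{(1)}` (the shot term also
  scales with `n`, so the normalised spectral shape is n-independent).

### 1.3 Telegraph promoters

A gene switching between an on state (transcription at `k_TX`) and an off
state (silent), with arbitrary dwell-time distributions in each state, has
the state-indicator spectrum

```
S_xi(omega) = (2 / (<t_on> + <t_off>)) *
              Re[ (1 - psi~_on)(1 - psi~_off) / (1 - psi~_on psi~_off) ] / omega^2
```

and transcription-rate spectrum `S_RTX = k_TX^2 S_xi`
(`telegraph_state_spectrum`, `telegraph_rate_spectrum`).  For exponential
dwells with leaving rates `k_on-exit`, `k_off-exit` this reduces to the
classic two-state Lorentzian `2 p (1-p) s / (omega^2 + s^2)` with
`s = k_on-exit + k_off-exit`.  Multi-step off states (a chain of activation
steps) produce an interior spectral peak at the promoter cycling frequency
`~ 2 pi / (<t_on> + <t_off>)` — a cycle fingerprint that no exponential
telegraph can produce.

### 1.4 Hidden-state modulated rates

`ModulatedRate(k0, alpha, lam)` models a creation rate depending on a hidden
Ornstein–Uhlenbeck coordinate `Gamma` (zero mean, unit variance, relaxation
rate `lam`) through the lognormal link `R = k0 exp(alpha Gamma - alpha^2/2)`.
The rate TCF is `<R>^2 [exp(alpha^2 e^{-lam t}) - 1]`, and expanding the
exponential gives the FSRR as a convergent series of Lorentzians of widths
`m lam` (`ou_rate_spectrum`); the noise strength is
`eta^2 = Var R / <R>^2 = e^{alpha^2} - 1`.

`DichotomousRate` is the exactly solvable companion: `R(t)` jumps between
two levels with exponential switching (relaxation rate `lam`), matched to a
target `(mean, eta^2, lam)` via `from_moments`.  Its FSRR is the single
Lorentzian `2 Var lam / (omega^2 + lam^2)`.  It exists because thinning
simulation of the lognormal link becomes infeasible at large `eta^2` (the
rate distribution acquires enormous tails), while the dichotomous process
with the same first two moments and correlation time is exactly simulable at
any noise strength.

### 1.5 Gene-expression cascades and deconvolution

`simulate_gene_expression` builds promoter -> mRNA -> protein cascades:
transcription fires only while the promoter is on (constant `k_TX`, or
gated *and* modulated when `transcription` is a `ModulatedRate` /
`DichotomousRate`); mRNA decays at `gamma_m`; each mRNA is translated at
`k_TL` per molecule; protein decays at `gamma_p`.  Because each stage is a
first-order output of the one above, the spectral relation applies
recursively, and the chain can be inverted from protein data alone:

```
S_m(omega)    = [ (omega^2 + gamma_p^2) S_p - 2<R_TL> ] / k_TL^2
S_RTX(omega)  = (omega^2 + gamma_m^2) S_m - 2<R_TX>
```

(`mrna_spectrum_from_protein`, `transcription_rate_spectrum_from_mrna`).
`S_RTX` is a property of the promoter/transcription machinery only, so the
recovered spectrum is invariant under changes of the mRNA lifetime — a
strong internal consistency check implemented in the acceptance suite.

For gated + modulated ("vibrant") transcription the mean-scaled rate
spectrum decomposes as

```
S~_RTX = S~_xi + S~_k + (1/2pi) (S~_xi * S~_k)
```

(`vibrant_transcription_spectrum`): the gating term, the modulation term,
and their spectral convolution.  Slow, weak modulation preserves the
promoter-cycle peak; fast, strong modulation buries it — the spectral
signature distinguishing the two noise sources.

Two auxiliary results round out the translation stage:
`estimate_ktl_asymptote` uses
`omega^2 [ S_p / S_p0 - 1 ] -> k_TL gamma_m` (for `omega` well above all
cascade rates) to read the translation coefficient off the protein spectrum,
and `heterogeneous_translation_relation` propagates a static cell-to-cell
translation-rate heterogeneity `eta_TL^2` into the factor `(1 + eta_TL^2)`
multiplying the mRNA-driven part of the protein spectrum.

### 1.6 Synchronized counting

`simulate_synchronized_counting` measures `<n(t)>*`, the mean number of
events after synchronising every trajectory on an event at `t = 0`.  Its
derivative relaxes to `<R>` (renewal theorem), and
`rate_tcf_from_synchronized_counting` converts it to the rate TCF via
`<dR(t) dR(0)> = <R> d<n(t)>*/dt - <R>^2`, giving a time-domain route to the
FSRR that cross-validates the spectral one.

## 2. Simulators and generator realism

All simulators generate **exact event times** — there is no time-step
discretisation of the dynamics, only of the recording grid:

* Renewal creation draws waiting times from the exact distribution of each
  model (sums of exponentials, mixtures, Gamma variates, branching
  turnover cycles) and accumulates epochs until the window is covered.
* Every product molecule receives an independent exponential lifetime at
  birth; counts on the recording grid are computed by binary search over
  the sorted birth/death times (`_counts_on_grid`), so recorded counts are
  the exact molecule numbers at the sample instants.
* Promoter trajectories alternate exact on/off dwell draws; transcription
  events while on are placed by inverse sampling within the on intervals.
* Translation is an inhomogeneous Poisson process with rate
  `k_TL * m(t)`: between consecutive mRNA birth/death events the rate is
  constant, so event counts per interval are exact Poisson draws placed
  uniformly (`_piecewise_poisson_times`).  This was verified against
  brute-force fine-grained thinning on identical mRNA paths.
* OU-modulated creation uses the exact OU update
  `Gamma_{n+1} = e^{-lam dt} Gamma_n + sqrt(1 - e^{-2 lam dt}) N(0,1)` on a
  thinning grid, firing events with probability `R(Gamma) dt`.  Thinning is
  the one approximate algorithm in the package; the simulator *aborts*
  (rather than silently degrading) if `R dt` ever exceeds 0.1.

Randomness: `SimRun(seed, n_traj, t_total, dt_record, burn_in)` spawns one
independent child generator per trajectory from a `SeedSequence`, so results
are reproducible bit-for-bit, independent of execution order, and extending
`n_traj` preserves the existing trajectories.  Every simulator warns if
`burn_in` is shorter than five times the slowest relaxation time it can see
in its parameters; stationarity of the retained window is tested in the
suite.

## 3. Estimator conventions

* Spectra are **two-sided** densities reported on `omega > 0` (angular
  frequency, rad per time unit).  With this convention
  `Var z = (1/2pi) Integral_{-inf}^{inf} S_z domega`, which is the Parseval
  check used in the tests.
* `estimate_fspn` averages per-trajectory (or per-Welch-segment)
  rectangular-window periodograms `(dt^2 / T) |DFT dz|^2` on the Fourier
  grid `omega_k = 2 pi k / T`; deviations are taken from the ensemble grand
  mean, the `k = 0` bin is excluded, and per-bin standard errors over
  segments are stored in `meta["stderr"]`.
* `estimate_tcf` / `spectrum_from_tcf` provide the time-domain route
  (biased autocovariance, trapezoidal cosine transform) and warn when the
  TCF has not decayed at the last lag.

### 3.1 Finite-sampling correction of the shot background

A periodogram of counts sampled every `dt` over a window `T = N dt` does not
estimate `S_z(omega)` but the aliased, Fejér-windowed expectation

```
E[I(omega)] = dt * Sum_{|m| < N} (1 - |m|/N) C(m dt) cos(omega m dt).
```

Relative to the true spectrum this carries (i) an aliasing excess growing as
`(omega / omega_Nyquist)^2` (reaching ~150% of the true Lorentzian floor at
the Nyquist frequency for a typical `gamma dt = 0.05`), and (ii) a
window-leakage bias `~ 2 Var(z) / (T omega^2)` from the triangular factor.
Both are negligible for the broad low-frequency features but *not* for the
FSRR extraction, where the subtraction `(omega^2 + gamma^2) S_z - 2<R>`
amplifies any high-frequency excess by `omega^2`.

For the Poisson background the correction is exactly computable: the shot
part of the count TCF is `(<R>/gamma) e^{-gamma |t|}`, and the windowed lag
sum above has a closed form via geometric series
(`sampled_lorentzian_background`).  `extract_fsrr` therefore subtracts this
exact expected sampled background — instead of the ideal continuous
Lorentzian — whenever the input spectrum carries its sampling metadata
(`dt`, `T` from `estimate_fspn`).  With this correction the extracted FSRR
of a simulated Poisson process is statistically zero across the full band
up to `10 gamma` at `gamma dt = 0.05`; without it the band average sits
several standard errors above zero.  Analytic or reconstructed spectra
(no sampling metadata) use the ideal background, keeping
`extract_fsrr(fspn_from_fsrr(.))` an exact algebraic identity.

The correction fixes the *background* term only; the `S_R`-driven part of a
measured spectrum still aliases.  Studies that quantify small
high-frequency effects should keep the band of interest well below Nyquist
(see 4.3).

## 4. Parameters, units, defaults, and rationale

Rates are in inverse time units; time units are arbitrary but minutes are
the natural reading for the gene-expression defaults.  Frequencies are
angular (rad/time); the CLI offers `--hz` for cycles/time output.

### 4.1 Reference birth–death studies

The Poisson null and renewal studies use `gamma = 1` as the unit of time,
`<R> = 2 gamma` (mean count 2 — sparse, strongly discrete traces where
Gaussian intuition fails and the spectral machinery must work on raw
counts), 200 trajectories of length `T = 200/gamma` recorded at
`dt = 0.05/gamma`, with `burn_in = 20/gamma`.  These sizes put per-bin
periodogram noise at ~7% and band-mean noise at ~1%, so a 5% band-wise
agreement criterion on the FSPN is a ~4–5 sigma test, while keeping the
whole study under a few seconds.

### 4.2 Gene-expression defaults

`GeneExpressionParams` defaults in the bundled circadian-promoter config
(1/min units):

* promoter off state: 7 sequential activation steps, rates
  `k_1..k_6 = 0.0993`, `k_7 = 0.23` (mean inactive period ~64.8 min) —
  a multi-step activation chain whose near-deterministic cycle produces
  the interior mRNA spectral peak;
* promoter on state: exponential, leaving rate `0.3` (mean burst ~3.3
  min) — transcriptional bursts are short compared to the cycle; the
  peak location is insensitive to this choice, sitting at
  `~ 2 pi / 68 min ~ 0.09 rad/min`;
* `k_TX = 2` (on-state transcription), `gamma_m = 0.2` (5-min mRNA
  lifetime, destabilised reporter), `k_TL = 5`, `gamma_p = 0.05` (20-min
  protein lifetime): mean mRNA ~0.5–10 and protein ~50–1000 depending on
  promoter duty, spanning the realistic low-copy regime.

### 4.3 The k_TL recovery study

Reading `k_TL gamma_m` off the `omega^2 [S_p/S_p0 - 1]` asymptote is the
most bias-sensitive measurement in the package, because the `omega^2`
amplification turns the two sampling artefacts of §3.1 into multiplicative
errors on `k_TL`.  The packaged study (acceptance suite and script) is
designed from the bias formulas, not by trial:

* **fast reporter** `gamma_p = 0.5`: the protein Fano factor
  `1 + k_TL/(gamma_m + gamma_p)` drops from ~21 to ~8 and the count
  variance 25-fold, shrinking the window-leakage bias
  `~ Var(p)/(<R_TL> T)` to below 1% of the fit-band signal;
* **long window** `T = 4000` with 60 trajectories: leakage and
  Monte-Carlo error both fall as the window grows;
* **fine sampling** `dt = 0.05`: Nyquist at 62.8 rad/min, a factor ~20
  above the fit band `omega in [1.5, 3]`, making the aliasing excess
  `(omega/omega_N)^2 < 0.3%`;
* **near-constitutive promoter** (on 100 min / off 1 min): no promoter
  structure inside or near the fit band.

With this design the recovery is unbiased within its standard error
(5.02 ± 0.14 for true `k_TL = 5`).  The earlier, slower-reporter design
(`gamma_p = 0.05`, `dt = 0.25`, `T = 2000`) overestimates `k_TL` more than
two-fold — an instructive failure retained here as a warning: the asymptote
estimator requires `omega_band << omega_Nyquist` *and*
`Var(p) << <R_TL> T * (k_TL gamma_m / <omega^2>_band)`.

## 5. Numerical choices

* **Renewal FSRR at low frequency.**  `Re[psi~/(1 - psi~)]` suffers
  catastrophic cancellation as `omega -> 0` (both numerator and
  denominator are `O(omega)` with nearly equal phases); relative accuracy
  degrades as `(k/omega)^2` epsilon.  Closed-form comparisons at the
  `1e-12` level are therefore made on grids with `omega >~ k/2`; below
  that the absolute error stays at the `1e-10 * <R>` level, which is
  irrelevant for any statistical use.
* **Lorentzian series for the OU-modulated FSRR** is summed until terms
  fall below `1e-14` of the accumulated value; validated against direct
  cosine-weighted quadrature (`scipy.integrate.quad` with
  `weight="cos"`) to better than `1e-8` relative.
* **Vibrant convolution term.**  The convolution
  `(S~_xi * S~_k)(omega)` is evaluated by adaptive quadrature with the
  integrand split at the peaks of both factors, on an 80-point
  logarithmic frequency grid, then log-log interpolated; validated
  against the closed-form convolution of two Lorentzians to `2e-3`,
  far below the Monte-Carlo noise of any simulated comparison.
* **Gamma dwell approximation.**  `gamma_approx_offtime` moment-matches a
  multi-step chain by a Gamma distribution: exact for equal-rate chains,
  and for mixed-rate chains the transform mismatch grows only as
  `omega^3` at low frequency.
* Writers emit floats through `repr(float(x))`, so TSV round trips are
  byte-exact and spectra/trajectories reload to the last ulp.

## 6. Open design choices

* **Two-sided spectra on the positive half-axis** (rather than one-sided
  densities): keeps `S_R = (omega^2+gamma^2) S_z - 2<R>` literally exact
  with `2<R>` as the shot floor, at the cost of a factor 2 versus
  engineering conventions; the Parseval test pins the normalisation.
* **Rectangular windows by default.**  Tapering (Hann) would suppress the
  leakage of §3.1 generically, but the exact sampled-background
  correction makes the dominant artefact vanish without sacrificing the
  rectangular window's resolution and simple error model.  Tapered
  estimation is a possible extension.
* **Tool shape.**  The package is a library of simulators, estimators and
  closed forms plus a thin `click` CLI on TSV/YAML files, not a
  fit/predict object: nothing here has tunable state learned from data.
* **mRNA-count spectrum includes shot noise.**  `S_m` throughout denotes
  the spectrum of the mRNA *number*, so the cascade deconvolution needs
  no knowledge of the transcription mechanism; the mechanism appears only
  at the final `S_RTX` step.

## 7. Limitations

* The FSPN/FSRR separation assumes first-order degradation with a rate
  independent of the creation machinery; saturating (enzymatic)
  degradation or feedback from `z` onto `R` breaks the exact relation.
* Thinning simulation of lognormal OU modulation is limited to moderate
  noise strength (`eta^2 <~ 1` at practical step sizes); use
  `DichotomousRate` as the strong-noise surrogate.
* The sampled-background correction removes sampling bias of the shot
  term only; the `S_R`-driven part of a measured FSPN still aliases, so
  quantitative high-frequency work must keep the analysis band well
  below Nyquist.
* Very slow modulation (`lam T <~ 10`) leaves finite-window bias in the
  lowest frequency bins; the estimators report per-bin errors but do not
  model this bias.
* `estimate_tcf` uses the biased (divide-by-N) autocovariance; for lags
  approaching the window length the TCF route is not reliable, and
  `spectrum_from_tcf` warns when the TCF has not decayed.
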