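# growthpeaks

Time-derivative analysis of bacterial growth curves from multimode microplate
readers.

Plate readers measure optical density (OD600) and bulk fluorescence (FL) of
growing cultures every few minutes, but two problems frustrate the classic
sigmoid-fitting workflow: multiple scattering bends the OD curve away from the
sigmoid shape at high density, and reagents under study (e.g. silver
nanoparticles) can scatter or absorb light themselves, injecting artifacts
into the OD channel. `growthpeaks` implements an analysis that sidesteps
both: instead of fitting the curve, it locates the bell-shaped peak of the
**first time derivative of OD** (the moment of fastest growth) and of the
**second time derivative of FL** (the moment of fastest acceleration of
fluorescent-protein accumulation). The peak locations track the culture's lag
time and the peak heights its maximum growth rate, while the distorted
high-density regime only contributes a harmless shoulder to the right of the
peak.

## The model behind the calibration

The relation between peak properties and growth parameters is calibrated on a
coupled ODE model. Cells start dormant and activate at rate α; active cells
grow logistically:

    dn_D/dt = −α n_D
    dn_A/dt = +α n_D + k₀ (1 − n_A/N) n_A ,        n = n_D + n_A

Active cells produce GFP at rate g per cell; non-fluorescent protein p_n
matures into fluorescent p_f at rate k_m, and both forms are degraded by
shared machinery with rate γ saturating at capacity M:

    dp_n/dt = g n_A − k_m p_n − γ p_n/(p_n + p_f + M)
    dp_f/dt = k_m p_n − γ p_f/(p_n + p_f + M)

All rates are hr⁻¹; counts are dimensionless. n is the proxy for OD, p_f for
FL. Lag time λ and maximum specific growth rate μ come from the modified
Gompertz (Zwietering) fit of the log-relative curve:

    ln(n(t)/n(0)) = A · exp{ −exp[ μe/A (λ − t) + 1 ] }

Sweeping one model parameter at a time and summarizing the derivative peaks
(location τ_p, τ_pf; height η_p, η_pf) yields the dependency relations that
justify reading growth properties off the peaks — for example, τ_p and τ_pf
are linear in λ with a common slope close to one, and η_p is exactly linear
in k₀.

## Worked example

```python
import growthpeaks as gp

traj = gp.simulate(dt=0.01)                     # default parameters:
                                                # α=1, k0=1 /hr, N=2e9,
                                                # g=100, km=1.5, γ=500, M=2e11
n  = gp.Curve(traj.times, traj.n,  label="n")
pf = gp.Curve(traj.times, traj.pf, label="pf")

od_peak = gp.find_peak(gp.forward_diff(n))
fl_peak = gp.find_peak(gp.forward_diff(gp.forward_diff(pf)))
fit     = gp.fit_gompertz(n)

print(f"tau_p  = {od_peak.tau:.2f} h   eta_p  = {od_peak.eta:.3e}")
print(f"tau_pf = {fl_peak.tau:.2f} h   eta_pf = {fl_peak.eta:.3e}")
print(f"lambda = {fit.lam:.3f} h   mu = {fit.mu:.3f} /hr")
```

prints

```
tau_p  = 3.62 h   eta_p  = 5.000e+08
tau_pf = 4.17 h   eta_pf = 4.648e+10
lambda = 0.619 h   mu = 0.868 /hr
```

The growth-rate peak sits at 3.62 h and its height is k₀N/4 = 5×10⁸ (the
logistic maximum); the fluorescence-acceleration peak lags it by 0.55 h, the
signature of GFP maturation. The Gompertz lag of 0.62 h is shorter than τ_p
by roughly the time the culture needs to climb from takeoff to half capacity.

The same pipeline runs on measured or synthetic plate data from the shell:

```
growthpeaks synth --seed 1 --out plate.csv        # synthetic 3-replicate plate
growthpeaks analyze --in plate.csv --out results/ # correct, aggregate, peaks, fits
growthpeaks reproduce --out calibration/          # all calibration sweeps
```

`analyze` applies the 2.39 path-length correction, aggregates replicate wells
(mean ± SEM), Hann-smooths (11-point window), differences, summarizes peaks,
and fits the Gompertz model to the OD channel truncated at corrected OD ≤ 1.0.

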