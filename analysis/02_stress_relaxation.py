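#!/usr/bin/env python
"""Relaxation-modulus estimation from synthetic stress fluctuations.

Injection-recovery at desk scale: stress series are generated with known
target moduli (a two-decade power law with exponent -0.45, and a single
Maxwell tail exp(-2t/4.088 ns)), pushed through the fluctuation estimator
with the multiple-tau correlator, and the slope / terminal-time fitters are
checked against the planted truth.

Writes results/gt_powerlaw.tsv and results/gt_maxwell.tsv.
"""

from pathlib import Path

from dendrorelax.io import write_curve_tsv
from dendrorelax.stress import (
    fit_loglog_slope,
    fit_tail_time,
    relaxation_modulus,
    window_from_levels,
)
from dendrorelax.synthetic.gpstress import PronySeries, generate_stress_gp, prony_from_powerlaw

OUT = Path("results")
OUT.mkdir(exist_ok=True)
SEED = 1

# --- power-law window, exponent -0.45 over t in [10, 1000] ps -------------
target = prony_from_powerlaw(-0.45, (10.0, 1000.0), amplitude=100.0)
series = generate_stress_gp(target, dt=0.5, n_frames=1 << 21,
                            volume=1000.0, temperature=600.0, seed=SEED)
curve = relaxation_modulus(series)
write_curve_tsv(curve, OUT / "gt_powerlaw.tsv")
slope, err = fit_loglog_slope(curve.times, curve.values, (10.0, 1000.0))
print(f"power-law window: planted exponent -0.45, "
      f"recovered {slope:.3f} +- {err:.3f}")

# --- Maxwell tail, tau_max = 4.088 ns (scaled-down length) ----------------
tau_max_ps = 4088.0
maxwell = PronySeries(((100.0, tau_max_ps / 2.0),))
series = generate_stress_gp(maxwell, dt=50.0, n_frames=1 << 21,
                            volume=1000.0, temperature=600.0, seed=SEED + 1)
curve = relaxation_modulus(series)
write_curve_tsv(curve, OUT / "gt_maxwell.tsv")
window = window_from_levels(curve, 0.01, 0.2)
fit = fit_tail_time(curve, window)
print(f"Maxwell tail: planted tau_max 4.088 ns, fitted {fit.tau_max_ns:.3f} ns "
      f"on window {window[0]:.0f}..{window[1]:.0f} ps "
      f"(residual rms {fit.residual_rms:.3f})")
print("note: single short replicas here; scripts/acceptance.py averages "
      "longer replicas, shrinking the Monte-Carlo error to ~1-2%")
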