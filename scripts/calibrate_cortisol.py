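"""One-off calibration of the synthetic diurnal cortisol curve.

The daily free-cortisol microdialysis samples behind the published curve
are not available, so the packaged synthetic curve pins the printed nadir
(1.45 nM at 03:00) and leaves two free constants: the morning peak height
and the post-peak exponential decay width.  This script tunes those two
constants so that the full time-dependent receptor model, driven by the
curve, reproduces the two published summary statistics of endogenous
cortisol pharmacodynamics:

  * peak relative transcriptional activity on day 2  = 0.39
  * daily glucocorticoid transcription quotient GTQ  = 0.17

and prints the values to freeze into ``grkin.profiles``
(CALIBRATED_PEAK_NM, CALIBRATED_DECAY_TAU_MIN).

Run from the repository root:  python scripts/calibrate_cortisol.py
"""

from scipy.optimize import least_squares

from grkin import default_rates, get_ligand
from grkin.dynamics import SimProtocol, simulate
from grkin.gtq import compute_gtq
from grkin.profiles import DiurnalCortisolSpec, synthetic_cortisol

TARGET_PEAK_ACTIVITY = 0.39
TARGET_GTQ = 0.17

rates = default_rates()
cortisol = get_ligand("cortisol").params


def summary(peak_nM: float, tau: float) -> tuple[float, float]:
    spec = DiurnalCortisolSpec(peak_nM=peak_nM, decay_tau_min=tau)
    prof = synthetic_cortisol(spec)
    traj = simulate(cortisol, rates, SimProtocol(profile=prof, t_end=2880.0))
    peak_act = float(traj.relative_activity[traj.time >= 1440.0].max())
    gtq = compute_gtq(cortisol, rates, prof, method="dynamic").value
    return peak_act, gtq


def residuals(x):
    peak_act, gtq = summary(*x)
    return [peak_act - TARGET_PEAK_ACTIVITY, gtq - TARGET_GTQ]


if __name__ == "__main__":
    sol = least_squares(residuals, x0=[33.0, 250.0],
                        bounds=([5.0, 30.0], [200.0, 1200.0]),
                        xtol=1e-10, ftol=1e-12, diff_step=1e-4)
    peak, tau = sol.x
    peak_act, gtq = summary(peak, tau)
    print(f"peak_nM = {peak:.4f}   decay_tau_min = {tau:.4f}")
    print(f"-> peak relative activity = {peak_act:.5f} (target {TARGET_PEAK_ACTIVITY})")
    print(f"-> GTQ                    = {gtq:.5f} (target {TARGET_GTQ})")
    print("\nFreeze in src/grkin/profiles.py:")
    print(f"CALIBRATED_PEAK_NM = {round(peak, 2)}")
    print(f"CALIBRATED_DECAY_TAU_MIN = {round(tau, 1)}")
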