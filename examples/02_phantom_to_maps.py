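"""Full image-space roundtrip on a small noisy phantom.

Simulates DCE, VFA and DWI series for a 16×16×1 phantom with an
ellipsoidal tumor at rician SNR 20, then runs the complete fitting
chain: VFA T1 map → concentration conversion → voxelwise Tofts fit
with physiological filtering → ADC map → ROI summaries.
"""

import numpy as np

from toftskit import (
    AcquisitionParams, AIFModel, DwiStack, GridGeometry, PhantomSpec,
    RelaxometryConfig, add_noise, build_phantom, concentration_from_signal,
    fit_adc, fit_t1_vfa, fit_tofts_map, simulate_dce, simulate_dwi,
    simulate_vfa, summarize_adc, summarize_roi,
)
from toftskit.pipeline import noise_sigma_for_snr

acq = AcquisitionParams(grid=GridGeometry(16, 16, 1))
aif, relax = AIFModel(), RelaxometryConfig()
spec = PhantomSpec(grid=acq.grid, semi_axes_mm=(0.25, 0.25, 0.3))
truth, roi = build_phantom(spec)

rng = np.random.default_rng(0)
dce = simulate_dce(truth, aif, acq, relax)
sigma = noise_sigma_for_snr(dce, acq.n_baseline, snr=20.0, roi=roi)
dce_n = add_noise(dce, "rician", sigma, rng)
vfa_n = add_noise(simulate_vfa(truth["T1"], truth["M0"], acq), "rician", sigma, rng)
dwi_n = add_noise(simulate_dwi(truth["ADC"], truth["M0"], acq.b_values),
                  "rician", sigma, rng)

t1, m0, t1_ok = fit_t1_vfa(vfa_n, acq.vfa_angles_deg, acq.tr_ms)
conc, _ = concentration_from_signal(dce_n, acq.n_baseline,
                                    np.where(t1_ok, t1, 1.0), relax, acq)
maps, valid = fit_tofts_map(conc, acq.times_s() / 60.0, aif, roi & t1_ok)
adc, _, adc_ok = fit_adc(DwiStack(acq.b_values, dwi_n, acq.grid))

print(f"tumor ROI: {int(roi.sum())} voxels, {int(valid.sum())} pass the filters")
for name, true_val in [("Ktrans", 0.41), ("Ve", 0.32), ("Vp", 0.06)]:
    s = summarize_roi(maps[name], roi, valid)
    print(f"{name:6s} median {s.median:.3f} (IQR {s.q1:.3f}-{s.q3:.3f}), truth {true_val}")
s = summarize_adc(adc, roi, adc_ok)
print(f"ADC    median {s.median:.2f} (IQR {s.q1:.2f}-{s.q3:.2f}) x1e-4 mm^2/s, truth 7.62")
# ROI medians land within a few percent of the generating values even
# at SNR 20, which is what makes the cohort-level comparisons meaningful.
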