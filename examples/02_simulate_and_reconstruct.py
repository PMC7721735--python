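"""Simulate one recording session and reconstruct the active fascicle.

A three-fascicle phantom is drawn, the tibial fascicle's conductivity is
raised by 0.05% with a stimulus-locked time course, raw 6 kHz recordings
are synthesized with channel noise sized for averaged-trace SNR ≈ 17, and
the full chain (demodulate → average → QC → Tikhonov → z-score → filter →
FWHM center of mass) localizes the activity.
"""

import numpy as np

from neureit.phantom import ActivityEvent, make_phantom
from neureit.pipeline import NerveSystem, simulate_and_reconstruct
from neureit.signal import cap_metrics

system = NerveSystem.build()
phantom = make_phantom(seed=42)
event = ActivityEvent(fascicle="tibial", fractional_change=5e-4)

result, recording, error_um = simulate_and_reconstruct(
    system, phantom, event, seed=42, target_snr=17.0, n_trials=20
)

truth = phantom.fascicle("tibial").center_xy_um()
com = result.com
print(f"traces: {len(result.traces)} total, {len(result.retained)} retained after QC")
print(f"peak averaged δV at t = {result.peak_time_ms:.2f} ms, "
      f"best-channel SNR {result.snr_max:.1f}")
print(f"true tibial center:      ({truth[0]:7.1f}, {truth[1]:7.1f}) µm")
print(f"reconstructed CoM:       ({com.x_um:7.1f}, {com.y_um:7.1f}) µm "
      f"(R = {com.r_um:.0f} µm, θ = {com.theta_deg:.0f}°)")
print(f"localization error: {error_um:.1f} µm "
      f"= {error_um / 1400 * 100:.1f}% of nerve diameter")

# response metrics of the strongest retained trace
best = max(result.retained, key=lambda t: np.abs(t.dv_uv).max())
m = cap_metrics(best, stim_distance_m=0.015)
print(f"strongest trace: peak {m.peak_uv:.2f} µV, onset {m.onset_ms:.2f} ms, "
      f"duration above 30% of peak {m.duration30_ms:.2f} ms, "
      f"conduction velocity {m.conduction_velocity_m_s:.0f} m/s, "
      f"SNR {m.snr_linear:.1f} ({m.snr_db:.1f} dB)")
# The onset reflects the 0.7 ms event latency; at a 1.5 cm stimulation
# distance that corresponds to fast myelinated fibers (tens of m/s).
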