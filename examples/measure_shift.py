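"""Measure a known couch shift from simulated Cherenkov images.

Simulates the matched AP photon (6 MV) and electron (10 MeV) fields on a
yellow tissue phantom, introduces a 5 mm inferior shift of the photon field,
and measures it back from the composite difference image.
"""

from cherimatch import (
    AcquisitionSpec,
    BeamSpec,
    ShiftSpec,
    TissueSpec,
    measure_matching,
    simulate_condition,
)

photon = BeamSpec("photon", 6.0)
electron = BeamSpec("electron", 10.0)
tissue = TissueSpec("yellow")
acq_p = AcquisitionSpec.default_for(photon, tissue)
acq_e = AcquisitionSpec.default_for(electron, tissue)

photon_ref = simulate_condition(photon, tissue, acq_p, None, rng_seed=0)
electron_ref = simulate_condition(electron, tissue, acq_e, None, rng_seed=1)
shifted = simulate_condition(
    photon, tissue, acq_p, ShiftSpec(5.0, "inferior", "photon"), rng_seed=2
)

result = measure_matching(photon_ref, electron_ref, photon_stack_shifted=shifted)
print(f"introduced shift : {result.introduced_shift_mm:+.1f} mm (+ = inferior)")
print(f"measured matching: {result.measured_matching_mm:.2f} mm")
print(f"discrepancy      : {result.discrepancy_mm:+.2f} mm")
print(f"band SNR         : {result.snr:.1f}")
# The measured matching value is the FWHM of the junction difference band
# converted to mm; the discrepancy is its error versus the known couch shift.
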