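"""Mean grayscale value (MGV) across beam energies and dose rates.

Computes the in-field mean intensity of noiseless images for every electron
energy and photon mode: MGV rises with electron energy (superficial dose is
roughly linear in energy) and with photon dose rate (FFF modes).
"""

from cherimatch import BeamSpec, TissueSpec, ideal_fluence_map, mean_grayscale
from cherimatch.metrics import default_metric_roi

tissue = TissueSpec("yellow")

print("electron fields (1.2 s integration):")
roi = default_metric_roi("electron")
for energy in (4.0, 6.0, 8.0, 10.0, 12.0, 15.0):
    img = ideal_fluence_map(BeamSpec("electron", energy), tissue, integration_time_s=1.2)
    print(f"  {energy:5.1f} MeV  MGV = {mean_grayscale(img, roi):8.1f}")

print("photon fields (1.0 s integration):")
roi = default_metric_roi("photon")
for beam, label in [
    (BeamSpec("photon", 6.0), " 6 MV  conventional"),
    (BeamSpec("photon", 10.0), "10 MV  conventional"),
    (BeamSpec("photon", 6.0, 1200.0, fff_flag=True), " 6 FFF 1200 MU/min"),
    (BeamSpec("photon", 10.0, 2400.0, fff_flag=True), "10 FFF 2400 MU/min"),
]:
    img = ideal_fluence_map(beam, tissue)
    print(f"  {label}  MGV = {mean_grayscale(img, roi):8.1f}")
# MGV is the arithmetic mean over a rectangle covering the field; units are
# 16-bit grayscale counts, relative (no absolute dose calibration).
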