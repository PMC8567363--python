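"""Fit Lorentzian line shapes and compare cis/trans resonance widths.

Simulates a 1-D trace with a broad (trans-like) and a narrow (cis-like)
resonance plus noise, fits a two-peak Lorentzian model and reports the full
widths at half maximum.
"""

import numpy as np

from vcss import LorentzianPeak, fit_lorentzians, simulate_spectrum

axis = np.linspace(3.0, 5.0, 1200)
truth = [LorentzianPeak(center=3.6, fwhm=0.12, amplitude=1.0),   # trans-like
         LorentzianPeak(center=4.4, fwhm=0.04, amplitude=1.0)]   # cis-like
spectrum = simulate_spectrum(truth, noise_sd=0.01, seed=3, axis=axis)

peaks, residual = fit_lorentzians(spectrum, n_peaks=2)
for p, tag in zip(peaks, ("trans-like", "cis-like")):
    print(f"{tag}: center {p.center:.3f} ppm, FWHM {p.fwhm * 1000:.1f} mppm, "
          f"amplitude {p.amplitude:.2f}")
print(f"residual norm {residual:.3f}")
print(f"FWHM ratio (trans/cis) = {peaks[0].fwhm / peaks[1].fwhm:.2f}")
print("\nA ratio above 1 reproduces the broader line of the trans resonance,")
print("consistent with its exchange between compact and extended tail states.")
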