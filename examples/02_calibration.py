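"""Instrument calibration with a fluorescein standard.

A real FLIM system rotates and shrinks every phasor (timing offsets,
finite instrument response).  Measuring a mono-exponential standard of
known lifetime — fluorescein at pH 9, 4.04 ns — pins down that transform
so it can be divided out of every pixel.  Here we distort a simulated
standard by a known shift and show the calibration recovering it.
"""

import numpy as np

from flimcyte import (AcquisitionParams, fit_calibration, phasor_of_histogram,
                      simulate_reference, single_exp_phasor)

acq = AcquisitionParams()
true_shift = (0.30, 0.90)  # phase offset (rad), modulation factor

hist = simulate_reference(4.04, 1e6, acq, instrument_shift=true_shift,
                          noiseless=True)
measured = phasor_of_histogram(hist, acq)
analytic = single_exp_phasor(4.04e-9, acq.omega)
cal = fit_calibration(measured, 4.04e-9, acq.omega)

print(f"analytic fluorescein phasor: g={analytic[0]:.4f} s={analytic[1]:.4f}")
print(f"measured (shifted) phasor:   g={measured[0]:.4f} s={measured[1]:.4f}")
print(f"fitted phase offset:        {cal.phase_offset:+.4f} rad "
      f"(true {true_shift[0]:+.2f})")
print(f"fitted modulation factor:    {cal.modulation_factor:.4f} "
      f"(true {true_shift[1]:.2f})")
print("\nThe fitted transform matches the imposed distortion to within the "
      "256-bin\ndiscretization; applying its inverse returns pixels to their "
      "true phasor locations.")
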