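"""Decays to phasors: where pure and mixed NAD(P)H species land.

Builds noiseless TCSPC histograms for free NAD(P)H (0.4 ns), a bound-like
species (3.2 ns) and a 50/50 intensity mixture, and prints their phasor
coordinates and phase/modulation lifetimes.  Pure species sit on the
universal semicircle; the mixture sits midway along the chord between
them, which is what makes the bound fraction readable as a distance.
"""

import numpy as np

from flimcyte import (AcquisitionParams, DecaySpec, make_decay_histogram,
                      phasor_of_histogram)

acq = AcquisitionParams()  # 80 MHz, 256 bins over one 12.5 ns period
omega = acq.omega

for label, alpha in [("free NAD(P)H (0.4 ns)", 0.0),
                     ("bound NAD(P)H (3.2 ns)", 1.0),
                     ("50/50 mixture", 0.5)]:
    hist = make_decay_histogram(DecaySpec(alpha_bound=alpha, photons=1e6),
                                acq, noiseless=True)
    g, s = phasor_of_histogram(hist, acq)
    tau_p = (s / g) / omega * 1e9
    tau_m = np.sqrt(1 / (g * g + s * s) - 1) / omega * 1e9
    on_circle = abs(s * s - g * (1 - g))
    print(f"{label:25s} g={g:.4f} s={s:.4f} "
          f"TauP={tau_p:.3f} ns TauM={tau_m:.3f} ns "
          f"|semicircle residual|={on_circle:.2e}")

print("\nPure species: TauP = TauM and the residual is ~0 (on the "
      "semicircle).\nThe mixture lies inside it, so TauP < TauM — the "
      "signature of a multi-exponential decay.")
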