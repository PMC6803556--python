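"""Physical constants and unit conversions used throughout the package.

All public APIs take strictly SI inputs (s, m, T); human-readable reports
convert to the conventional clinical units (s/mm^2, mT/m, ms).
"""

# Proton gyromagnetic ratio [rad s^-1 T^-1].
GYROMAGNETIC_RATIO = 267.513e6

# Shell clustering default: 50 s/mm^2 in SI units [s/m^2]; separates clinical
# shells spaced >= 200 s/mm^2 while absorbing vendor jitter in reported b.
DEFAULT_SHELL_DISTANCE = 50e6

# Measurements whose b is below this are treated as b0 [s/m^2] (10 s/mm^2).
B0_THRESHOLD = 10e6

SI_TO_SMM2 = 1e-6      # s/m^2 -> s/mm^2
SI_TO_MTM = 1e3        # T/m   -> mT/m
SI_TO_MS = 1e3         # s     -> ms
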