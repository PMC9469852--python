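"""Published per-FA area-% of the SPE fractions (NL, FFA, PL) of wild and
farmed Atlantic salmon, with the printed class-subtotal rows, used as the
oracle for reconstructing class sums within each fraction.

Values are (wild NL, wild FFA, wild PL, farmed NL, farmed FFA, farmed PL);
None = not detected.
"""

FRACTION_COMPOSITION = {
    "C12:0":                    (0.071, 0.09, None, None, None, None),
    "C13:0 (4,8,12-trimethyl)": (0.09, None, None, None, None, None),
    "C14:0":                    (4.28, 3.70, 0.97, 2.05, 2.88, 0.62),
    "C14:0 (13-methyl)":        (0.19, 0.15, None, 0.05, None, None),
    "C14:0 (12-methyl)":        (0.13, 0.10, None, 0.03, None, None),
    "C15:0":                    (0.42, 0.34, 0.23, 0.140, 0.26, 0.13),
    "C16:0":                    (18.08, 22.96, 22.86, 9.49, 19.14, 20.62),
    "C17:0":                    (0.57, 0.36, 0.53, 0.21, 0.32, 0.29),
    "C18:0":                    (3.67, 5.43, 4.01, 2.59, 7.55, 1.57),
    "C20:0":                    (0.10, 0.10, None, 0.283, 0.220, 0.08),
    "C22:0":                    (None, None, None, 0.08, None, None),
    "C24:0":                    (None, None, None, 0.07, None, None),
    "C16:1n-9c":                (0.15, 0.13, None, 0.137, 0.13, 0.12),
    "C16:1n-7c":                (6.22, 4.43, 1.05, 2.32, 2.06, 0.46),
    "C16:1n-5c":                (0.27, 0.30, None, None, None, None),
    "C17:1n-7c":                (0.24, 0.22, None, 0.098, None, None),
    "C18:1n-12c":               (0.86, 0.92, 0.64, 0.17, None, None),
    "C18:1n-9c":                (17.76, 11.52, 7.42, 44.65, 28.34, 11.04),
    "C18:1n-7c":                (4.14, 3.44, 1.98, 3.04, 2.68, 1.78),
    "C18:1n-5c":                (0.28, 0.27, None, None, None, None),
    "C20:1n-11c":               (0.89, 0.48, 0.23, 0.19, None, None),
    "C20:1n-9c":                (7.54, 3.85, 1.24, 3.24, 1.67, 0.31),
    "C20:1n-7c":                (0.26, 0.15, None, 0.11, None, None),
    "C22:1n-9c":                (8.07, 3.27, 0.30, 1.26, 0.46, 0.11),
    "C24:1n-9c":                (0.60, 0.29, None, 0.07, 0.26, 0.28),
    "C16:2n-4c":                (0.27, 0.18, None, 0.17, 0.20, None),
    "C18:2n-6c":                (1.08, 0.77, 0.34, 14.40, 13.88, 2.84),
    "C18:3n-6c":                (None, None, None, 0.08, None, None),
    "C18:3n-3c":                (0.88, 0.67, 0.20, 6.23, 7.13, 2.45),
    "C18:4n-3c":                (1.23, 0.79, 0.21, 0.49, 0.43, 0.13),
    "C20:2n-6c":                (0.24, 0.15, None, 0.774, 0.61, 0.30),
    "C20:3n-6c":                (0.06, 0.05, None, 0.18, 0.15, 0.20),
    "C20:3n-3c":                (0.19, 0.14, None, 0.34, 0.31, 0.18),
    "C20:4n-6c":                (0.29, 0.55, 0.60, 0.13, 0.16, 0.56),
    "C20:4n-3c":                (1.33, 1.05, 0.44, 0.56, 0.55, 0.49),
    "C20:5n-3c":                (6.32, 10.72, 8.15, 2.08, 4.30, 8.90),
    "C21:5n-3c":                (0.38, 0.24, 0.31, 0.04, 0.116, 0.15),
    "C22:5n-3c":                (2.67, 2.39, 2.84, 1.05, 0.66, 2.50),
    "C22:6n-3c":                (10.08, 19.81, 44.44, 2.61, 3.88, 39.46),
}

COLUMNS = (
    ("wild", "NL"), ("wild", "FFA"), ("wild", "PL"),
    ("farmed", "NL"), ("farmed", "FFA"), ("farmed", "PL"),
)

# printed subtotal rows, same column order
PRINTED_SUBTOTALS = {
    "SFA":  (27.62, 33.21, 28.60, 15.00, 30.37, 23.30),
    "MUFA": (47.29, 29.27, 12.86, 55.27, 35.60, 14.09),
    "PUFA": (25.00, 37.49, 57.53, 29.15, 32.38, 58.16),
    "n-3":  (23.06, 35.79, 56.60, 13.40, 17.37, 54.26),
    "n-6":  (1.67, 1.52, 0.94, 15.57, 14.81, 3.90),
}
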