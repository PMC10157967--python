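"""Published per-frequency statistics of the darkness-vs-light contrast.

The 23 analysis frequencies (printed truncated to 3 decimals), the
permutation p-values, and the FDR-corrected significance flags of the
oscillatory-power comparison between planarians recorded during darkness
and under light stimulation.  These serve as a frozen reference for the
frequency-grid builder and as input to the FDR-procedure check: the
Benjamini-Yekutieli step-up applied to these p-values must reproduce the
significance flags exactly (plain Benjamini-Hochberg does not — it
additionally flags 1.342 and 2.319-2.685 Hz).
"""

FREQS = [
    0.488, 0.610, 0.732, 0.854, 0.976, 1.098, 1.342, 1.586, 1.953, 2.319,
    2.685, 3.173, 3.784, 4.394, 5.249, 6.225, 7.324, 8.666, 10.253, 12.084,
    14.282, 16.967, 20.019,
]

DARK_VS_LIGHT_P = [
    0.0001, 0.0001, 0.0001, 0.0001, 0.0001, 0.0001, 0.0050, 0.0831, 0.0168,
    0.0035, 0.0027, 0.0007, 0.0001, 0.0001, 0.0001, 0.0001, 0.0001, 0.0001,
    0.0001, 0.0001, 0.0001, 0.0001, 0.0001,
]

DARK_VS_LIGHT_SIG = [
    True, True, True, True, True, True, False, False, False, False, False,
    True, True, True, True, True, True, True, True, True, True, True, True,
]
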