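"""Bundled device-validation readings.

Paired bedside readings comparing the tri-wavelength acquisition device
against a commercial pulse oximeter (three volunteers, three repeats
each): blood oxygen saturation in percent and heart rate in bpm.  Used by
the paired-error check in :func:`ppgrehab.vitals.paired_error_table`.
"""

#: (device SpO2 %, reference SpO2 %) per measurement
SPO2_PAIRS = [
    (98, 98), (98, 97), (96, 97),
    (95, 95), (99, 100), (97, 97),
    (95, 96), (97, 97), (100, 100),
]

#: (device HR bpm, reference HR bpm) per measurement
HR_PAIRS = [
    (86, 86), (92, 93), (89, 89),
    (89, 90), (99, 100), (101, 100),
    (109, 108), (101, 101), (86, 85),
]
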