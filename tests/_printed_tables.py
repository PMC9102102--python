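"""Published summary tables of the long-term grassland fertilization study
the model was designed on, used as worked-example inputs.

Raw plate data of that study is not deposited, but its treatment-level
tables are: mean total activity per treatment, guild-level segment means,
the segment index rows, the functional-alteration column and the
guild-association pairs.  Feeding the printed aggregates through the
package's formulas must reproduce the printed derived rows.

Treatments: V1 unfertilized control; V2 manure; V3 manure + low mineral
NPK; V4 mineral NPK only; V5 manure + high mineral NPK.
"""

# Mean total substrate activity (OD sum over 31 substrates) per treatment.
TOTAL_ACTIVITY = {"V1": 50.7, "V2": 59.9, "V3": 54.2, "V4": 45.4, "V5": 48.9}

# Guild-level segment means (OD) per treatment: {segment: {treatment: {guild: mean}}}.
GUILD_MEANS = {
    "intensification": {
        "V2": {"AA": 0.98, "AM": 0.18, "CH": 1.23, "CX": 1.11, "P": 0.81},
        "V3": {"AA": 1.23, "AM": 0.08, "CH": 0.94, "CX": 1.23, "P": 0.44},
        "V4": {"AA": 1.01, "AM": 0.12, "CH": 0.60, "CX": 0.82, "P": 0.23},
        "V5": {"AA": 0.65, "AM": 0.09, "CH": 0.91, "CX": 0.65, "P": 0.14},
    },
    "narrowing": {
        "V2": {"AA": 0.15, "AM": 0.22, "CH": 0.63, "CX": 0.73, "P": 0.08},
        "V3": {"AA": 0.24, "AM": 0.25, "CH": 1.02, "CX": 0.87, "P": 0.41},
        "V4": {"AA": 0.49, "AM": 0.37, "CH": 1.36, "CX": 1.17, "P": 0.54},
        "V5": {"AA": 0.71, "AM": 0.24, "CH": 0.81, "CX": 1.27, "P": 0.57},
    },
    "expansion": {
        "V2": {"AA": 0.77, "AM": 0.10, "CH": 2.83, "CX": 1.65, "P": 2.11},
        "V3": {"AA": 0.91, "AM": 0.11, "CH": 1.90, "CX": 1.65, "P": 1.05},
        "V4": {"AA": 0.79, "AM": 0.07, "CH": 0.46, "CX": 1.61, "P": 0.17},
        "V5": {"AA": 0.38, "AM": 0.10, "CH": 1.38, "CX": 0.63, "P": 0.62},
    },
    "contraction": {
        "V2": {"AA": 0.01, "AM": 0.00, "CH": 0.48, "CX": 0.27, "P": 0.02},
        "V3": {"AA": 0.55, "AM": 0.17, "CH": 1.64, "CX": 0.40, "P": 0.46},
        "V4": {"AA": 0.66, "AM": 0.92, "CH": 2.98, "CX": 2.02, "P": 0.67},
        "V5": {"AA": 0.57, "AM": 0.26, "CH": 0.84, "CX": 1.65, "P": 0.41},
    },
}

# Published segment index rows (percent of the treatment's own total activity).
PRINTED_INDICES = {
    "intensification": {"V2": 7.23, "V3": 7.26, "V4": 6.17, "V5": 5.03},
    "narrowing": {"V2": 3.07, "V3": 5.20, "V4": 8.74, "V5": 7.42},
    "expansion": {"V2": 12.4, "V3": 10.4, "V4": 6.79, "V5": 6.39},
    "contraction": {"V2": 1.36, "V3": 6.06, "V4": 16.0, "V5": 7.78},
}

# Published functional-alteration column (signed percent vs. control total).
PRINTED_FA = {"V2": 18.07, "V3": 6.92, "V4": -10.44, "V5": -3.53}

# Published guild-association pairs, per treatment, in segment order
# (intensification, narrowing, expansion, contraction).
PRINTED_GUILD_PAIRS = {
    "V2": {"intensification": "CH–CX", "narrowing": "CX–CH",
           "expansion": "CH–P", "contraction": "CH–CX"},
    "V3": {"intensification": "CX–AA", "narrowing": "CH–CX",
           "expansion": "CH–CX", "contraction": "CH–AA"},
    "V4": {"intensification": "AA–CX", "narrowing": "CH–CX",
           "expansion": "CX–AA", "contraction": "CH–CX"},
    "V5": {"intensification": "CH–CX", "narrowing": "CX–CH",
           "expansion": "CH–CX", "contraction": "CX–CH"},
}

# The two cells where guild means tie at the printed two-decimal precision
# (the pair is acceptable in either order there).
TIED_CELLS = {("V3", "intensification"), ("V5", "intensification")}
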