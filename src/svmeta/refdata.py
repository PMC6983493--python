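"""Published survey values for four large dsDNA virus populations.

These are the printed results of a deep-sequencing survey of structural
variation in populations of the baculovirus AcMNPV, the human
cytomegalovirus (HCMV) and two invertebrate iridescent viruses (IIV6,
IIV31).  They serve as worked-example inputs: per-type genome-affected
fractions recombine into total burdens, robust-SV counts check the
selection arithmetic, and the TE junction table checks totalling.  None
of these values feed back into the algorithms.
"""

from __future__ import annotations

#: Percentage of genomes affected by each SV type, per population.
PER_TYPE_GENOME_FRACTIONS_PCT: dict[str, dict[str, float]] = {
    "AcMNPV": {"DEL": 11.91, "DUP": 2.05, "INS": 26.11, "INV": 5.70},
    "HCMV": {"DEL": 12.43, "DUP": 9.69, "INS": 0.0, "INV": 42.30},
    "IIV6": {"DEL": 47.16, "DUP": 8.90, "INS": 0.0, "INV": 1.14},
    "IIV31": {"DEL": 76.58, "DUP": 0.11, "INS": 6.72, "INV": 8.60},
}

#: Printed percentage of genomes carrying at least one SV, per population.
TOTAL_GENOME_FRACTIONS_PCT: dict[str, float] = {
    "AcMNPV": 39.87,
    "HCMV": 54.37,
    "IIV6": 52.41,
    "IIV31": 80.06,
}

#: Robust SV counts per type in the AcMNPV population (both technologies).
ACMNPV_ROBUST_SV_COUNTS: dict[str, int] = {
    "DEL": 464,
    "INV": 443,
    "DUP": 160,
    "INS": 74,
}

#: SVs involving homologous regions (hr) in the AcMNPV population, per type.
ACMNPV_HR_SV_COUNTS: dict[str, int] = {
    "DEL": 103,
    "INV": 6,
    "DUP": 3,
    "INS": 2,
}

#: Total SVs detected in AcMNPV short reads, long reads, and the robust
#: (cross-technology) subset.
ACMNPV_SHORT_READ_SV_TOTAL = 22_892
ACMNPV_LONG_READ_SV_TOTAL = 9_421
ACMNPV_ROBUST_SV_TOTAL = 1_141

#: Per-superfamily TE junction counts in AcMNPV short reads:
#: (unique chimeric reads, reads including PCR duplicates, insertion
#: frequency in percent).
ACMNPV_TE_JUNCTIONS: dict[str, tuple[int, int, float]] = {
    "Sola": (2347, 2956, 0.7),
    "Harbinger": (1154, 1305, 0.3),
    "Gypsy": (495, 562, 0.13),
    "Mariner": (361, 1078, 0.24),
    "piggyBac": (349, 398, 0.09),
    "Copia": (180, 319, 0.07),
    "Transib": (51, 57, 0.01),
    "MuLE": (33, 35, 0.007),
    "Helitron": (22, 22, 0.005),
    "hAT": (1, 10, 0.002),
}
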