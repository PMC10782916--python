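"""Published co-occurrence results used as a regression oracle.

Each row: (gene_a, gene_b, sample, k observed events, adjusted p-value
for a single co-occurrence, estimated p-value for k events), as printed
(3 significant figures) in the study's co-occurrence table.  ``CLEAN``
marks rows whose estimated p recomputes exactly at 3 s.f. from the
printed adjusted p; the rest carry rounding of the printed inputs.
"""

TABLE_ROWS = [
    ("MACROD2", "BRAF", "a", 1, 3.02e-03, 3.02e-03),
    ("MACROD2", "BRAF", "b", 1, 3.34e-03, 3.34e-03),
    ("MACROD2", "BRAF", "c", 2, 6.59e-04, 4.34e-07),
    ("RBFOX1", "BRAF", "b", 1, 2.29e-03, 2.29e-03),
    ("RBFOX1", "BRAF", "c", 2, 8.30e-04, 6.88e-07),
    ("PTPRD", "WWC3", "b", 1, 2.58e-03, 2.58e-03),
    ("PTPRD", "WWC3", "c", 2, 2.38e-04, 5.68e-08),
    ("NEDD4L", "BRAF", "a", 1, 9.56e-04, 9.56e-04),
    ("NEDD4L", "BRAF", "b", 3, 7.81e-04, 4.77e-10),
    ("NEDD4L", "ABCG2", "a", 1, 9.33e-04, 9.33e-04),
    ("NEDD4L", "ABCG2", "b", 2, 2.67e-04, 7.11e-08),
    ("NEDD4L", "TENM2", "a", 1, 2.96e-03, 2.96e-03),
    ("NEDD4L", "TENM2", "b", 2, 2.96e-03, 8.79e-06),
    ("TENM2", "BRAF", "a", 1, 1.43e-03, 1.43e-03),
    ("TENM2", "BRAF", "b", 2, 2.33e-03, 5.44e-06),
    ("MITF", "LPAR1", "a", 3, 1.26e-03, 2.00e-09),
    ("OSBPL9", "FAM180A", "a", 2, 1.01e-03, 1.02e-06),
    ("SH3PXD2A", "WDR41", "a", 2, 8.40e-04, 7.06e-07),
    ("LOC105376514", "MITF", "a", 2, 7.20e-04, 5.18e-07),
    ("LOC105376514", "ATG10", "a", 2, 6.30e-04, 3.97e-07),
    ("TEAD1", "BRAF", "a", 2, 6.40e-04, 4.10e-07),
    ("CPNE8", "BRAF", "a", 2, 5.04e-04, 2.54e-07),
    ("CPNE8", "FBXO10", "a", 2, 4.58e-04, 2.10e-07),
    ("ABCC4", "ANXA4", "a", 2, 2.33e-04, 5.44e-08),
    ("DOK6", "NR2F1-AS1", "a", 2, 3.88e-04, 1.50e-07),
    ("ROCK2", "COLQ", "a", 2, 3.60e-04, 1.30e-07),
    ("RASGRP3", "MITF", "a", 2, 2.29e-04, 5.25e-08),
    ("LOC101927967", "MITF", "a", 2, 3.15e-04, 9.92e-08),
    ("LOC101927967", "SLC24A2", "a", 2, 2.96e-04, 8.79e-08),
    ("LOC101927967", "CNTNAP3B", "a", 2, 2.80e-04, 7.84e-08),
    ("LOC101927967", "LPAR1", "a", 2, 2.65e-04, 7.04e-08),
    ("PLCL1", "LOC105372948", "a", 2, 2.52e-04, 6.35e-08),
    ("SYN3", "HTR1F", "a", 2, 4.94e-04, 2.44e-07),
    ("MITF", "SLC24A2", "a", 2, 3.36e-04, 1.13e-07),
    ("PTPN13", "ATG10", "a", 2, 7.37e-04, 5.43e-07),
    ("ATG10", "NR2F1-AS1", "a", 2, 4.20e-04, 1.76e-07),
    ("TBXAS1", "BRAF", "a", 2, 5.60e-04, 3.14e-07),
    ("TBXAS1", "ST18", "a", 2, 1.68e-03, 2.82e-06),
    ("AGBL4", "NEDD4L", "b", 2, 2.80e-04, 7.84e-08),
    ("ANXA9", "ABCA11P", "b", 2, 2.52e-03, 6.35e-06),
    ("KIN", "LOC102724861", "b", 2, 3.86e-04, 1.49e-07),
    ("ITPR2", "LOC102723906", "b", 2, 5.60e-04, 3.14e-07),
    ("MGAT4C", "BRAF", "b", 2, 4.31e-04, 1.86e-07),
    ("HS3ST3A1", "NEDD4L", "b", 2, 2.24e-04, 5.02e-08),
    ("ITGA3", "LOC105377171", "b", 2, 3.36e-04, 1.13e-07),
    ("ITGA3", "GRB10", "b", 2, 3.29e-04, 1.09e-07),
    ("NEDD4L", "LOC102724861", "b", 2, 6.83e-04, 4.66e-07),
    ("NEDD4L", "ZC3H12B", "b", 2, 1.22e-03, 1.48e-06),
    ("LOC102724861", "TENM2", "b", 2, 1.15e-03, 1.31e-06),
    ("LOC102724861", "PDE1C", "b", 2, 8.00e-04, 6.40e-07),
    ("MACROD2", "TENM2", "b", 2, 1.41e-02, 1.99e-04),
    ("LOC105377171", "GRB10", "b", 2, 2.43e-04, 5.93e-08),
    ("LOC105377180", "KDM5C", "b", 2, 4.15e-04, 1.72e-07),
    ("KIAA1524", "MEGF9", "b", 2, 3.73e-04, 1.39e-07),
    ("IGSF11", "EYS", "b", 2, 5.08e-03, 2.58e-05),
    ("KALRN", "BRAF", "b", 2, 1.24e-03, 1.55e-06),
    ("ABCA11P", "LOC105374483", "b", 2, 1.68e-03, 2.82e-06),
    ("ABCG2", "BRAF", "b", 2, 5.42e-04, 2.94e-07),
    ("ABCG2", "NSMCE2", "b", 2, 5.89e-04, 3.47e-07),
    ("LOC102723906", "EYS", "b", 2, 3.38e-03, 1.14e-05),
    ("LOC105377865", "ZC3H12B", "b", 2, 2.14e-03, 4.60e-06),
    ("GRB10", "ZC3H12B", "b", 2, 6.05e-04, 3.67e-07),
    ("CNTNAP2", "ZC3H12B", "b", 2, 7.13e-03, 5.08e-05),
    ("SLC26A7", "ZFPM2-AS1", "b", 2, 4.80e-04, 2.30e-07),
]

# rows whose estimated p matches p_adj**k exactly at 3 s.f. from the
# printed (rounded) adjusted p
CLEAN = {
    ("MITF", "LPAR1", "a"),
    ("MACROD2", "BRAF", "c"),
    ("OSBPL9", "FAM180A", "a"),
    ("TEAD1", "BRAF", "a"),
    ("AGBL4", "NEDD4L", "b"),
}
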