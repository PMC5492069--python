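"""Published reference tables for the harlequin bug transcriptome survey.

These are the printed result tables of the *Murgantia histrionica* (harlequin
bug) whole-transcriptome study deposited under BioProject PRJNA302154:
per-sample Illumina sequencing volumes, the strongest per-contrast expression
fold changes among gold-tier transcripts, sex-preferential cytochrome P450
expression values, and TPM profiles of terpene-biosynthesis transcripts in
harlequin bug and the brown marmorated stink bug (*Halyomorpha halys*, BMSB).

They serve two purposes here: as worked-example inputs to the expression
module (every finite printed log2 ratio is re-derivable from its printed TPM
pair), and as regression anchors for the volume-accounting arithmetic.

Sentinel strings in ratio fields follow the fixed machine-readable spellings
used throughout this package: ``"undefined"`` (0/0), ``"+inf"`` and ``"-inf"``
(one-sided zero denominator/numerator).
"""

from __future__ import annotations

# --- Sequencing data volumes (read pairs / bases, raw and post-normalization).
# Paired-end strategy, targeted read length 100 bp, one bioreplicate per sample.
SEQUENCING_VOLUMES: dict[str, dict[str, int]] = {
    "2nd": {
        "read_pairs_raw": 213_817_714,
        "bases_raw": 42_763_542_800,
        "read_pairs_norm": 13_268_461,
        "bases_norm": 2_653_692_200,
    },
    "4th": {
        "read_pairs_raw": 222_117_185,
        "bases_raw": 44_423_437_000,
        "read_pairs_norm": 15_199_439,
        "bases_norm": 3_039_887_800,
    },
    "female": {
        "read_pairs_raw": 205_127_388,
        "bases_raw": 41_025_477_600,
        "read_pairs_norm": 11_786_560,
        "bases_norm": 2_357_312_000,
    },
    "male": {
        "read_pairs_raw": 218_215_787,
        "bases_raw": 43_643_157_400,
        "read_pairs_norm": 14_191_526,
        "bases_norm": 2_838_305_200,
    },
}

# Published column totals for the volumes above.
SEQUENCING_VOLUME_TOTALS: dict[str, int] = {
    "read_pairs_raw": 859_278_074,
    "bases_raw": 171_855_614_800,
    "read_pairs_norm": 54_445_986,
    "bases_norm": 10_889_197_200,
}

# --- Greatest fold changes per contrast among gold-tier transcripts.
# Each row: (contrast, printed |log2FC| to 4 dp, direction, TPM of the
# contrast's first-named sample, TPM of the second, NR gene annotation).
# A TPM floor of 5.0 was imposed on both samples of every reported row.
FOLD_CHANGE_ROWS: tuple[tuple[str, float, str, float, float, str], ...] = (
    ("2nd:4th", 5.1284, "up", 253.24, 7.24, "adult-specific cuticular protein ACP-20-like"),
    ("2nd:4th", 4.6366, "up", 1055.89, 42.45, "uncharacterized protein LOC106688964"),
    ("2nd:4th", 3.6726, "up", 366.36, 28.73, "tubulin beta-1 chain"),
    ("2nd:4th", 3.5047, "up", 380.01, 33.48, "protein takeout-like"),
    ("2nd:4th", 3.3727, "up", 192.25, 18.56, "GTP cyclohydrolase 1 isoform X1"),
    ("2nd:4th", 5.3563, "down", 8.17, 334.68, "heat shock 70 kDa protein cognate 4"),
    ("2nd:4th", 5.3279, "down", 7.17, 287.99, "acyl-CoA Delta(11) desaturase-like isoform X1"),
    ("2nd:4th", 5.2056, "down", 6.33, 233.59, "uncharacterized protein LOC106679388"),
    ("2nd:4th", 4.7751, "down", 9.21, 252.18, "lysosomal alpha-mannosidase"),
    ("2nd:4th", 4.6475, "down", 6.05, 151.63, "uncharacterized protein LOC106683993"),
    ("female:male", 4.1357, "up", 375.11, 21.34, "heat shock 70 kDa protein cognate 4"),
    ("female:male", 3.5908, "up", 104.22, 8.65, "JH acid O-methyltransferase-like isoform X1"),
    ("female:male", 2.8439, "up", 88.45, 12.32, "uncharacterized protein LOC106679932"),
    ("female:male", 2.7760, "up", 124.18, 18.13, "troponin C, isoform 1-like"),
    ("female:male", 2.7262, "up", 34.21, 5.17, "adult-specific cuticular protein ACP-20-like"),
    ("female:male", 3.9320, "down", 570.39, 8706.01, "putative odorant-binding protein 4"),
    ("female:male", 2.7080, "down", 5.58, 36.46, "E3 ubiquitin-protein ligase TRIM37-like isoform X2"),
    ("female:male", 2.2543, "down", 6.29, 30.01, "exocyst complex component 7"),
    ("female:male", 1.9412, "down", 6.51, 25.00, "DDB1- and CUL4-associated factor 6-like"),
    ("female:male", 1.9045, "down", 7.18, 26.88, "exosome complex component CSL4"),
    ("adults:nymphs", 3.8701, "up", 5288.23, 361.66, "putative odorant-binding protein 4"),
    ("adults:nymphs", 3.7040, "up", 105.04, 8.06, "inositol monophosphatase 2-like"),
    ("adults:nymphs", 3.4889, "up", 98.80, 8.80, "uncharacterized protein LOC106686819"),
    ("adults:nymphs", 3.4091, "up", 78.93, 7.43, "uncharacterized protein LOC106691169"),
    ("adults:nymphs", 3.0628, "up", 264.22, 31.62, "NADP-dependent malic enzyme-like isoform X3"),
    ("adults:nymphs", 6.0853, "down", 44.80, 3041.89, "uncharacterized protein LOC106688633"),
    ("adults:nymphs", 4.3486, "down", 5.41, 110.22, "pro-resilin-like"),
    ("adults:nymphs", 3.7376, "down", 13.83, 184.48, "probable antibacterial peptide"),
    ("adults:nymphs", 3.6876, "down", 9.00, 115.96, "cuticle protein 18.6, isoform B"),
    ("adults:nymphs", 3.2451, "down", 11.07, 104.96, "GTP cyclohydrolase 1 isoform X1"),
)

# --- Sex-preferential cytochrome P450 expression values.
# Each row: (TPM male, TPM female, printed |log2(male:female)| to 4 dp or a
# sentinel string, direction '+' = male-leaning / '-' = female-leaning,
# transcript id, best NR hit annotation).
SEX_PATTERN_ROWS: tuple[tuple[float, float, str, str, str, str], ...] = (
    (0.03, 18.87, "9.2969", "-", "472510", "XP_014270541.1 (CYP4GZ4)"),
    (0.07, 24.35, "8.4424", "-", "473495", "XP_014286441.1 (CYP6LT5)"),
    (0.40, 72.44, "7.5006", "-", "419699", "XP_014273208.1 (CYP6LT7)"),
    (0.06, 8.73, "7.1849", "-", "103772", "XP_014286439.1 (CYP6LT3)"),
    (0.27, 19.68, "6.1876", "-", "103769", "XP_014286439.1 (CYP6LT3)"),
    (6.35, 0.00, "undefined", "+", "478727", "XP_014293876.1 (CYP307B1)"),
    (4.71, 0.00, "undefined", "+", "173857", "XP_014285590.1 (CYP3226B1)"),
    (9.95, 0.01, "9.9586", "+", "298833", "XP_014293876.1 (CYP307B1)"),
    (4.30, 0.07, "5.9408", "+", "137898", "XP_014288222.1 (CYP3227B4)"),
    (3.26, 0.15, "4.4418", "+", "521147", "XP_014276563.1 (CYP3225B3)"),
    (5.85, 0.61, "3.2616", "+", "428429", "XP_014279285.1 (CYP302A1)"),
    (38.09, 6.24, "2.6098", "+", "103771", "XP_014286439.1 (CYP6LT3)"),
    (21.99, 6.92, "1.6680", "+", "504543", "XP_014284935.1 (CYP4HB7)"),
    (15.69, 5.20, "1.5933", "+", "456532", "XP_014285589.1 (CYP3226B1)"),
    (25.99, 8.88, "1.5493", "+", "486339", "XP_014285590.1 (CYP3226B1)"),
    (14.45, 5.10, "1.5025", "+", "316472", "XP_014274999.1 (CYP3224A2)"),
    (15.06, 5.51, "1.4506", "+", "165088", "XP_014271425.1 (CYP6LU1)"),
    (13.48, 6.26, "1.1066", "+", "212119", "XP_014284933.1 (CYP4HB6)"),
    (7.51, 15.33, "1.0295", "-", "504542", "XP_014284935.1 (CYP4HB7)"),
)

# --- Terpene-biosynthesis transcript TPM profiles with printed binary-log
# ratios (2 dp or sentinel). Each row:
# (species, annotation, TPM 2nd, TPM 4th, printed 4th:2nd,
#  TPM male, TPM female, printed female:male,
#  TPM nymphs, TPM adults, printed adults:nymphs, transcript/protein id)
TERPENE_EXPRESSION_ROWS: tuple[
    tuple[str, str, float, float, str, float, float, str, float, float, str, str], ...
] = (
    ("hbug", "Acetoacetyl-CoA thiolase", 176.92, 131.53, "-0.43", 211.58, 344.29, "0.70", 154.39, 267.85, "0.79", "HBug_USDA-ARS_IIBBL.267134"),
    ("hbug", "Acetoacetyl-CoA thiolase", 41.01, 28.64, "-0.52", 21.84, 33.13, "0.60", 34.61, 26.66, "-0.38", "HBug_USDA-ARS_IIBBL.43170"),
    ("hbug", "HMG-CoA reductase", 15.83, 12.42, "-0.35", 29.97, 22.95, "-0.39", 14.10, 27.05, "0.94", "HBug_USDA-ARS_IIBBL.421664"),
    ("hbug", "HMG-CoA synthase", 0.53, 0.60, "0.18", 0.27, 0.45, "0.74", 0.57, 0.35, "-0.70", "HBug_USDA-ARS_IIBBL.375421"),
    ("hbug", "Mevalonate kinase", 0.11, 0.28, "1.35", 0.05, 0.33, "2.72", 0.22, 0.13, "-0.76", "HBug_USDA-ARS_IIBBL.227208"),
    ("hbug", "Phosphomevalonate kinase", 4.51, 2.76, "-0.71", 6.08, 3.08, "-0.98", 3.59, 4.76, "0.41", "HBug_USDA-ARS_IIBBL.270718"),
    ("hbug", "Diphosphomevalonate decarboxylase", 0.05, 0.12, "1.26", 0.13, 0.11, "-0.24", 0.09, 0.14, "0.64", "HBug_USDA-ARS_IIBBL.428020"),
    ("hbug", "IDP Isomerase", 20.22, 10.48, "-0.95", 15.04, 13.73, "-0.13", 15.32, 14.53, "-0.08", "HBug_USDA-ARS_IIBBL.92242"),
    ("hbug", "FDP Synthase", 3.44, 0.41, "-3.07", 46.44, 3.51, "-3.73", 1.92, 28.48, "3.89", "HBug_USDA-ARS_IIBBL.420512"),
    ("hbug", "FDP Synthase", 25.04, 23.37, "-0.10", 32.47, 31.56, "-0.04", 23.79, 32.17, "0.44", "HBug_USDA-ARS_IIBBL.414919"),
    ("hbug", "Farnesol dehydrogenase", 0.16, 0.15, "-0.09", 0.00, 0.00, "undefined", 0.16, 0.00, "-inf", "HBug_USDA-ARS_IIBBL.414590"),
    ("hbug", "Farnesol dehydrogenase", 0.00, 0.13, "+inf", 0.07, 0.45, "2.68", 0.03, 0.15, "2.32", "HBug_USDA-ARS_IIBBL.328207"),
    ("hbug", "Farnesol dehydrogenase", 13.27, 9.88, "-0.43", 7.78, 7.54, "-0.05", 11.57, 7.81, "-0.57", "HBug_USDA-ARS_IIBBL.376500"),
    ("hbug", "Farnesal dehydrogenase", 0.29, 0.20, "-0.54", 8.14, 12.84, "0.66", 0.24, 10.14, "5.40", "HBug_USDA-ARS_IIBBL.14716"),
    ("hbug", "Farnesal dehydrogenase", 3.29, 9.14, "1.47", 4.99, 5.77, "0.21", 6.24, 5.30, "-0.24", "HBug_USDA-ARS_IIBBL.79640"),
    ("hbug", "Juvenile hormone acid methyltransferase", 0.04, 0.00, "-inf", 0.12, 0.03, "-2.00", 0.00, 0.09, "+inf", "HBug_USDA-ARS_IIBBL.519494"),
    ("hbug", "Juvenile hormone acid methyltransferase", 3.04, 10.78, "1.83", 4.97, 64.51, "3.70", 6.87, 30.65, "2.16", "HBug_USDA-ARS_IIBBL.485486"),
    ("hbug", "Juvenile hormone acid methyltransferase", 0.03, 1.22, "5.35", 0.09, 0.28, "1.64", 0.68, 0.17, "-2.00", "HBug_USDA-ARS_IIBBL.346622"),
    ("hbug", "Methyl farnesoate epoxidase", 0.39, 0.12, "-1.70", 0.18, 0.14, "-0.36", 0.25, 0.17, "-0.56", "HBug_USDA-ARS_IIBBL.517163"),
    ("bmsb", "Acetoacetyl-CoA thiolase", 175.06, 168.71, "-0.05", 793.94, 942.05, "0.25", 171.71, 864.84, "2.33", "XP_014294739.1"),
    ("bmsb", "Acetoacetyl-CoA thiolase", 70.48, 65.24, "-0.11", 147.12, 185.97, "0.34", 67.72, 165.71, "1.29", "XP_014275331.1"),
    ("bmsb", "HMG-CoA reductase", 18.12, 21.68, "0.26", 44.27, 25.96, "-0.77", 20.00, 35.52, "0.83", "XP_014280269.1"),
    ("bmsb", "HMG-CoA synthase", 0.00, 0.00, "undefined", 0.44, 1.40, "1.67", 0.00, 1.28, "+inf", "XP_014277503.1"),
    ("bmsb", "Mevalonate kinase", 8.00, 8.54, "0.09", 12.13, 7.82, "-0.63", 8.29, 10.07, "0.28", "XP_014272243.1"),
    ("bmsb", "Phosphomevalonate kinase", 5.97, 4.46, "-0.42", 7.02, 4.80, "-0.55", 5.17, 5.96, "0.21", "XP_014271961.1"),
    ("bmsb", "Diphosphomevalonate decarboxylase", 3.96, 3.44, "-0.20", 4.90, 3.98, "-0.30", 3.72, 4.46, "0.26", "XP_014290216.1"),
    ("bmsb", "IDP Isomerase", 13.51, 10.56, "-0.36", 11.89, 14.15, "0.25", 11.96, 12.97, "0.12", "XP_014271459.1"),
    ("bmsb", "FDP Synthase", 3.62, 8.08, "1.16", 15.70, 18.66, "0.25", 5.97, 17.12, "1.52", "XP_014276183.1"),
    ("bmsb", "FDP Synthase", 12.52, 14.96, "0.26", 13.13, 15.78, "0.27", 13.80, 14.40, "0.06", "XP_014276401.1"),
    ("bmsb", "FDP synthase", 0.04, 0.16, "2.00", 0.80, 0.04, "-4.32", 0.10, 0.44, "2.14", "XP_014289203.1"),
    ("bmsb", "FDP synthase", 0.29, 0.29, "0.00", 0.35, 0.22, "-0.67", 0.29, 0.28, "-0.05", "XP_014289225.1"),
    ("bmsb", "Farnesol dehydrogenase", 204.63, 77.01, "-1.41", 35.70, 46.26, "0.37", 137.30, 40.68, "-1.75", "XP_014286519.1"),
    ("bmsb", "Farnesol dehydrogenase", 78.56, 47.27, "-0.73", 43.79, 43.94, "0.00", 62.05, 43.86, "-0.50", "XP_014286524.1"),
    ("bmsb", "Farnesol dehydrogenase", 107.93, 53.10, "-1.02", 44.15, 27.32, "-0.69", 79.01, 36.10, "-1.13", "XP_014286525.1"),
    ("bmsb", "Farnesal dehydrogenase", 28.66, 94.12, "1.72", 35.72, 49.72, "0.48", 63.19, 42.42, "-0.57", "XP_014272618.1"),
    ("bmsb", "Farnesal dehydrogenase", 49.42, 54.55, "0.14", 57.72, 65.03, "0.17", 52.13, 61.22, "0.23", "XP_014292700.1"),
    ("bmsb", "Juvenile hormone acid methyltransferase", 0.13, 0.06, "-1.12", 0.22, 34.99, "7.31", 0.09, 16.85, "7.55", "XP_014293044.1"),
    ("bmsb", "Juvenile hormone acid methyltransferase", 46.90, 45.31, "-0.05", 22.24, 79.28, "1.83", 46.06, 49.52, "0.10", "XP_014290953.1"),
    ("bmsb", "Juvenile hormone acid methyltransferase", 0.38, 0.34, "-0.16", 0.79, 0.18, "-2.13", 0.36, 0.50, "0.47", "XP_014283772.1"),
    ("bmsb", "Methyl farnesoate epoxidase", 1.15, 0.59, "-0.96", 0.16, 0.26, "0.70", 0.86, 0.21, "-2.03", "XP_014283057.1"),
)


def iter_printed_ratios():
    """Yield every printed binary-log ratio with its TPM pair.

    Yields tuples ``(source, numerator_tpm, denominator_tpm, printed, dp)``
    where ``printed`` is either a float (finite ratio, signed as printed) or
    a sentinel string, and ``dp`` is the printed decimal precision.

    For the fold-change table the printed value is a magnitude; it is
    re-signed here from the stated direction so every yielded float equals
    log2(numerator/denominator) at the printed precision.
    """
    for contrast, mag, direction, tpm_a, tpm_b, _gene in FOLD_CHANGE_ROWS:
        signed = mag if direction == "up" else -mag
        yield ("fold_change", tpm_a, tpm_b, signed, 4)
    for tpm_m, tpm_f, printed, _direction, _put, _hit in SEX_PATTERN_ROWS:
        if printed in ("undefined", "+inf", "-inf"):
            continue  # notational inconsistency in source; see methods note
        # printed magnitude of log2(male:female)
        mag = float(printed)
        signed = mag if tpm_m >= tpm_f else -mag
        yield ("sex_pattern", tpm_m, tpm_f, signed, 4)
    for row in TERPENE_EXPRESSION_ROWS:
        (_sp, _ann, t2, t4, r42, tm, tf, rfm, tn, ta, ran, _tid) = row
        for num, den, printed in ((t4, t2, r42), (tf, tm, rfm), (ta, tn, ran)):
            if printed in ("undefined", "+inf", "-inf"):
                yield ("terpene", num, den, printed, 2)
            else:
                yield ("terpene", num, den, float(printed), 2)
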