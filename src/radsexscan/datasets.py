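"""Published zebrafish *AB x Nadia cross inputs used as worked examples.

Small printed tables from the mapped reciprocal F2 intercross between the
*AB and Nadia wild-type zebrafish strains: family sex counts, the
genotype-by-sex table at the chr-4 sex-associated peak marker, and the
Zv9 repetitive-element copy numbers for the chr-4q heterochromatic region.
These are inputs for the statistics in this package, not outputs of it.
"""

from __future__ import annotations

import pandas as pd

#: Fraction of the Zv9 assembly covered by the chr-4q heterochromatic region.
CHR4_HETEROCHROMATIN_FRACTION = 0.0226

#: Zv9 coordinates of the chr-4q heterochromatic region (approximate start)
#: and the chromosome end.
CHR4_HET_REGION = ("chr4", 28_000_000, 62_094_675)


def cross_family_sex_counts() -> pd.DataFrame:
    """F2 sex counts of the two reciprocal families (all sexed offspring)."""
    return pd.DataFrame({
        "family": ["A", "B"],
        "grandsire_strain": ["*AB", "Nadia"],
        "n_male": [103, 96],
        "n_female": [86, 56],
        "n_mapped": [145, 86],
        "n_mapped_male": [82, 48],
        "n_mapped_female": [63, 38],
    })


def sar4_peak_genotype_counts() -> pd.DataFrame:
    """Genotype-by-sex counts at the Family-A chr-4 peak marker (C/G SNP).

    All 70 C/C homozygotes were male; 63 of the 75 C/G heterozygotes were
    female.  The mapped family comprises 82 males and 63 females.
    """
    return pd.DataFrame({
        "genotype": ["C/C", "C/G"],
        "n_male": [70, 12],
        "n_female": [0, 63],
    })


def chr4q_element_counts() -> pd.DataFrame:
    """Repetitive-element copy numbers: genome-wide and in chr-4q heterochromatin (Zv9)."""
    rows = [
        ("ENSFM00650001139997 (zinc finger)", 436, 261),
        ("ENSFM00500000269617", 417, 185),
        ("ENSFM00610000952917", 147, 97),
        ("ENSFM00250000000002 (zinc finger)", 189, 54),
        ("ENSFM00500000273896 (ms4a17a)", 16, 15),
        ("ENSFM00600000925039", 12, 11),
        ("ENSFM00600000923389", 13, 8),
        ("miRNA mir-430", 56, 55),
        ("snRNA U6", 706, 460),
        ("snRNA U1", 382, 224),
        ("tRNA", 22_275, 10_396),
        ("Kolobok 1", 4_445, 635),
        ("Pseudogenes", 200, 24),
    ]
    return pd.DataFrame(rows, columns=["element_class", "n_genome", "observed"])
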