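"""Small built-in datasets used by the documentation and worked examples."""

from __future__ import annotations

import pandas as pd

# Published putative-enhancer-SNP / GWAS-SNP pairs for blood-lipid loci
# with their HapMap-CEU r^2 (chromosome, eSNP, GWAS tag SNP, r^2, trait,
# association p). Applying the strong-LD filter (r^2 >= 0.8, D' >= 0.9 via
# the sqrt(r^2) lower bound) to these rows leaves 7 unique eSNPs.
_ESNP_GWAS_LD_PAIRS = [
    ("1", "rs17315646", "rs10489615", 0.97, "HDL", 4e-9),
    ("1", "rs17315646", "rs2144300", 1.00, "HDL", 3e-14),
    ("1", "rs17315646", "rs4846914", 1.00, "HDL", 2e-13),
    ("9", "rs2575875", "rs4149268", 0.96, "HDL", 1e-10),
    ("9", "rs3847301", "rs3890182", 0.81, "HDL", 3e-10),
    ("9", "rs3847301", "rs3905000", 0.81, "HDL", 9e-13),
    ("9", "rs643531", "rs643531", 1.00, "HDL", 7e-9),
    ("11", "rs12287066", "rs12272004", 0.83, "TC", 7e-7),
    ("11", "rs12287066", "rs12286037", 1.00, "TG", 1e-26),
    ("11", "rs12287066", "rs28927680", 1.00, "TG", 2e-17),
    ("16", "rs1109166", "rs12449157", 0.94, "HDL", 2e-7),
    ("19", "rs2075650", "rs2075650", 1.00, "TC", 3e-19),
]


def esnp_gwas_ld_pairs() -> pd.DataFrame:
    """The published (eSNP, GWAS SNP, r^2) pairs for the blood-lipid loci.

    Columns: chrom, proxy_snp (the eSNP), seed_snp (the GWAS tag), r2,
    trait, p_value.  D' was not printed alongside; the strong-LD filter
    handles that via the algebraic D' >= sqrt(r^2) lower bound.
    """
    df = pd.DataFrame(_ESNP_GWAS_LD_PAIRS, columns=[
        "chrom", "proxy_snp", "seed_snp", "r2", "trait", "p_value"])
    df["d_prime"] = float("nan")
    return df
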