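"""Bundled example assay count tables for *Perca* sex markers.

Published genotyping counts for sex diagnostics in European perch
(*Perca fluviatilis*) and Balkhash perch (*P. schrenkii*): PCR
presence/absence markers scored in several wild and aquaculture populations,
and seven KASPar allele-specific assays (SNV1-SNV7) targeting single
sex-specific variants inside the chromosome-18 sex-determining region.
These serve as worked-example inputs for :mod:`sdscan.linkstats`.
"""

from __future__ import annotations

from .linkstats import GenotypeCountTable

__all__ = ["PRESENCE_MARKERS", "KASPAR_ASSAYS", "KASPAR_COHORT_SIZE"]

#: Presence/absence PCR markers: assay id -> (pos_m, n_m, pos_f, n_f).
#: ``amhr2bY_alakol`` is the P. schrenkii Y-duplicate screen (one fish per
#: sex); the others are P. fluviatilis assays on the hsdl1 intronic indel and
#: the SNV1 KASPar variant scored as dominant presence markers.
PRESENCE_MARKERS: dict[str, tuple[int, int, int, int]] = {
    "amhr2bY_alakol": (1, 1, 0, 1),
    "hsdl1_mueggelsee": (10, 10, 0, 9),
    "snv1_lucasperche": (48, 48, 0, 47),
    "snv1_kortowskie": (17, 17, 0, 20),
}

#: Recruited cohort for the KASPar panel: 48 males + 48 females.
KASPAR_COHORT_SIZE = 96

#: KASPar Ho/He/U counts per sex for the seven assays.
KASPAR_ASSAYS: tuple[GenotypeCountTable, ...] = (
    GenotypeCountTable("SNV1", male_ho=0, male_he=48, male_u=0, female_ho=47, female_he=0, female_u=0),
    GenotypeCountTable("SNV2", male_ho=8, male_he=37, male_u=3, female_ho=34, female_he=2, female_u=12),
    GenotypeCountTable("SNV3", male_ho=0, male_he=45, male_u=0, female_ho=48, female_he=0, female_u=0),
    GenotypeCountTable("SNV4", male_ho=0, male_he=46, male_u=2, female_ho=46, female_he=0, female_u=2),
    GenotypeCountTable("SNV5", male_ho=0, male_he=42, male_u=2, female_ho=46, female_he=0, female_u=2),
    GenotypeCountTable("SNV6", male_ho=1, male_he=47, male_u=0, female_ho=25, female_he=2, female_u=18),
    GenotypeCountTable("SNV7", male_ho=1, male_he=46, male_u=0, female_ho=45, female_he=3, female_u=0),
)
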