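"""The miR-200-family mini-panel used in the worked examples.

Mature miRBase-style sequences for the human miRNAs whose seed
relationships anchor the analysis: miR-429 and miR-200b share the seed
AAUACUG; miR-141 differs from miR-429 by one seed nucleotide (mature
position 4); miR-205 differs by five (positions 2, 3, 5, 7 and 8);
miR-25 and miR-32 are a second identical-seed family (AUUGCAC).
"""

from .seed import MatureMiRNA

MIR200_FAMILY_SEQUENCES: dict[str, str] = {
    "hsa-miR-429": "UAAUACUGUCUGGUAAAACCGU",
    "hsa-miR-200b": "UAAUACUGCCUGGUAAUGAUGA",
    "hsa-miR-141": "UAACACUGUCUGGUAAAGAUGG",
    "hsa-miR-205": "UCCUUCAUUCCACCGGAGUCUG",
    "hsa-miR-25": "CAUUGCACUUGUCUCGGUCUGA",
    "hsa-miR-32": "UAUUGCACAUUACUAAGUUGCA",
}


def study_panel() -> list[MatureMiRNA]:
    """The six-miRNA worked-example panel as MatureMiRNA records."""
    return [MatureMiRNA(id=k, sequence=v) for k, v in MIR200_FAMILY_SEQUENCES.items()]
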