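"""Shared fixtures: the miR-200-family study panel and small file writers.

Mature sequences are miRBase-style and match the miRNAs used throughout the
analyses (the miR-429/miR-141/miR-205 trio with seeds differing by 1 and 5
nucleotides, the identical-seed families miR-429/miR-200b and
miR-25/miR-32). All fixtures are generated programmatically; nothing is
read from disk except what a test itself writes to tmp_path.
"""

from __future__ import annotations

import pytest

from mirseedcost import MatureMiRNA

MATURE_SEQUENCES = {
    "hsa-miR-429": "UAAUACUGUCUGGUAAAACCGU",
    "hsa-miR-200b": "UAAUACUGCCUGGUAAUGAUGA",
    "hsa-miR-141": "UAACACUGUCUGGUAAAGAUGG",
    "hsa-miR-205": "UCCUUCAUUCCACCGGAGUCUG",
    "hsa-miR-25": "CAUUGCACUUGUCUCGGUCUGA",
    "hsa-miR-32": "UAUUGCACAUUACUAAGUUGCA",
}


@pytest.fixture(scope="session")
def study_panel() -> list[MatureMiRNA]:
    return [MatureMiRNA(id=k, sequence=v) for k, v in MATURE_SEQUENCES.items()]


@pytest.fixture(scope="session")
def mirna() -> dict[str, MatureMiRNA]:
    return {k: MatureMiRNA(id=k, sequence=v) for k, v in MATURE_SEQUENCES.items()}


@pytest.fixture
def write_fasta(tmp_path):
    def _write(records: dict[str, str], name: str = "seqs.fa"):
        path = tmp_path / name
        path.write_text("".join(f">{k}\n{v}\n" for k, v in records.items()))
        return path

    return _write
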