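"""Mature miRNA sequence registry and FASTA loading.

The bundled sequences are the mature human miRNAs most relevant to
methyl-mark profiling, as distributed in miRBase release 21.  Methylated
positions are always user input, never constants.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict

from Bio import SeqIO

from .rna_mass import Oligo

__all__ = ["MIRBASE_R21", "get_mirna", "load_fasta"]

#: Mature sequences, miRBase release 21.
MIRBASE_R21: Dict[str, str] = {
    "hsa-miR-17-5p": "CAAAGUGCUUACAGUGCAGGUAG",
    "hsa-miR-21-5p": "UAGCUUAUCAGACUGAUGUUGA",
    "hsa-miR-21-3p": "CAACACCAGUCGAUGGGCUGU",
    "hsa-miR-200c-3p": "UAAUACUGCCGGGUAAUGAUGGA",
    "hsa-let-7a-5p": "UGAGGUAGUAGGUUGUAUAGUU",
}


def get_mirna(mirna_id: str, **oligo_kwargs) -> Oligo:
    """Bundled mature miRNA as an :class:`Oligo` (default mature termini)."""
    try:
        seq = MIRBASE_R21[mirna_id]
    except KeyError:
        raise KeyError(
            f"unknown miRNA {mirna_id!r}; bundled ids: {sorted(MIRBASE_R21)}"
        ) from None
    return Oligo(seq, **oligo_kwargs)


def load_fasta(path: str | Path) -> Dict[str, str]:
    """Read RNA sequences from FASTA (T is treated as U)."""
    return {
        rec.id: str(rec.seq).upper().replace("T", "U")
        for rec in SeqIO.parse(str(path), "fasta")
    }
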