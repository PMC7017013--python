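#!/usr/bin/env python
"""Fetch protein sequences for a study registry from NCBI (network required).

The library itself never touches the network; this helper exists for users
who want to run the pipeline on a real protein family.  Given a registry TSV
(id, species, subfamily, accession) it downloads each accession's protein
record via NCBI E-utilities and writes a FASTA keyed by registry id:

    python scripts/fetch_study_sequences.py --registry study.tsv \
        --email you@example.org --out study.fasta

Sequences are taken as-is (use the longest isoform's accession in the
registry).  Not used by any test.
"""

from __future__ import annotations

import argparse
import time
from pathlib import Path


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--registry", type=Path, required=True)
    parser.add_argument("--out", type=Path, required=True)
    parser.add_argument("--email", required=True, help="NCBI E-utilities contact")
    args = parser.parse_args()

    from Bio import Entrez, SeqIO

    Entrez.email = args.email
    rows = []
    for line in args.registry.read_text().splitlines():
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        rec_id, _species, _subfamily, accession = line.split("\t")
        rows.append((rec_id.strip(), accession.strip()))

    with open(args.out, "w") as fh:
        for rec_id, accession in rows:
            with Entrez.efetch(db="protein", id=accession,
                               rettype="fasta", retmode="text") as handle:
                seq_rec = SeqIO.read(handle, "fasta")
            fh.write(f">{rec_id}\n{seq_rec.seq}\n")
            print(f"{rec_id}\t{accession}\t{len(seq_rec.seq)} aa")
            time.sleep(0.4)  # NCBI rate limit


if __name__ == "__main__":
    main()
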