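#!/usr/bin/env python
"""Download the ten tephritid mitogenomes from NCBI (network required).

The bundled data files cover the annotation table and the per-gene class
statistics; full-sequence analyses (genome-wide composition, RSCU, the
G+C-rich/A+T-rich codon ratio, control-region motif coordinates) need the
GenBank records themselves. This script fetches them via NCBI E-utilities
into GenBank flat files readable by ``mitocomp.genome.read_genbank``.

Usage:  python scripts/fetch_genomes.py --out scratch/genomes [--email you@example.org]
"""

from __future__ import annotations

import argparse
import time
from pathlib import Path
from urllib.parse import urlencode
from urllib.request import urlopen

ACCESSIONS = {
    "HM776033": "Bactrocera minax",
    "AY210702": "Bactrocera oleae",
    "HQ130030": "Bactrocera tryoni",
    "DQ995281": "Bactrocera philippinensis",
    "EF014414": "Bactrocera carambolae",
    "DQ917578": "Bactrocera papayae",
    "DQ845759": "Bactrocera dorsalis",
    "AJ242872": "Ceratitis capitata",
    "JX456552": "Bactrocera correcta",
    "JN635562": "Bactrocera cucurbitae",
}

EFETCH = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"


def fetch(accession: str, email: str | None) -> str:
    params = {
        "db": "nuccore",
        "id": accession,
        "rettype": "gbwithparts",
        "retmode": "text",
    }
    if email:
        params["email"] = email
    with urlopen(f"{EFETCH}?{urlencode(params)}") as resp:
        return resp.read().decode()


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=Path("scratch/genomes"))
    parser.add_argument("--email", default=None, help="Contact email for NCBI etiquette.")
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    for accession, species in ACCESSIONS.items():
        target = args.out / f"{accession}.gb"
        if target.exists():
            print(f"{accession} ({species}): already present")
            continue
        print(f"fetching {accession} ({species}) ...")
        target.write_text(fetch(accession, args.email))
        time.sleep(0.4)  # NCBI rate etiquette
    print(f"done: {len(ACCESSIONS)} records under {args.out}")


if __name__ == "__main__":
    main()
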