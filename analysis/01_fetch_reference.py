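#!/usr/bin/env python
"""Fetch the deposited coordinate sets used by the reference analyses.

Downloads 3ASI (the LNS5-EGF3-LNS6 neurexin fragment), 1C4R (Nrx1β
LNS), 1DYK (laminin α2 LNS5), and the two Nrx1β/neuroligin-1 2:2
complexes 3B3Q and 3BIW into data/reference/.  Requires network
access; every downstream script and the reference test block read from
that directory and report clearly when it is empty.
"""

import sys
import urllib.request
from pathlib import Path

ENTRIES = ["3asi", "1c4r", "1dyk", "3b3q", "3biw"]
OUT = Path(__file__).resolve().parents[1] / "data" / "reference"
URL = "https://files.rcsb.org/download/{}.pdb"


def main() -> int:
    OUT.mkdir(parents=True, exist_ok=True)
    failures = []
    for pdb_id in ENTRIES:
        dest = OUT / f"{pdb_id}.pdb"
        if dest.exists():
            print(f"{pdb_id}: already present")
            continue
        try:
            urllib.request.urlretrieve(URL.format(pdb_id.upper()), dest)
            print(f"{pdb_id}: fetched ({dest.stat().st_size // 1024} KB)")
        except OSError as exc:
            failures.append(pdb_id)
            print(f"{pdb_id}: FAILED ({exc})")
    if failures:
        print(f"\ncould not fetch: {', '.join(failures)} — check network access",
              file=sys.stderr)
        return 1
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
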