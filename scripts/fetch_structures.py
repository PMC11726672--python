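#!/usr/bin/env python
"""Download the μ-opioid-receptor ensemble PDB files (explicit opt-in).

The library itself never downloads anything; this helper exists so a
user with network access can materialize the experimental structure
set listed in ``confensemble/data/mor_chains.json`` and then run, e.g.::

    python scripts/fetch_structures.py --out-dir structures/
    confensemble pca structures/manifest.json --out-dir pca_out/

Usage:
    python scripts/fetch_structures.py --out-dir structures/
"""

from __future__ import annotations

import argparse
import json
import urllib.request
from importlib import resources
from pathlib import Path

RCSB = "https://files.rcsb.org/download/{pdb_id}.pdb"


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-dir", type=Path, required=True)
    ap.add_argument("--chains", type=Path, default=None,
                    help="JSON chain list (default: the packaged receptor set).")
    args = ap.parse_args()

    if args.chains is not None:
        entries = json.loads(args.chains.read_text())
    else:
        ref = resources.files("confensemble").joinpath("data/mor_chains.json")
        entries = json.loads(ref.read_text())

    args.out_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    seen: set[str] = set()
    for e in entries:
        pdb_id = e["pdb_id"].upper()
        dest = args.out_dir / f"{pdb_id}.pdb"
        if pdb_id not in seen and not dest.exists():
            print(f"fetching {pdb_id} ...")
            urllib.request.urlretrieve(RCSB.format(pdb_id=pdb_id), dest)
        seen.add(pdb_id)
        manifest.append({"path": dest.name, "chain": e["chain"],
                         "label": e.get("label", f"{pdb_id}_{e['chain']}")})
    (args.out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    print(f"wrote {args.out_dir / 'manifest.json'}")


if __name__ == "__main__":
    main()
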