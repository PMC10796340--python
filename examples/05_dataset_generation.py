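"""Generate a scaled-down dataset tree and verify its manifest.

The default full run covers 92 patients x 4 movements = 368 TRC motion
files, each with 6 MAS-grade STO simulation bundles (2,208 samples). Here
two patients give the same tree shape in seconds. Every file is hashed
into manifest.csv; verify_dataset re-hashes and re-parses to prove the
tree is intact and reproducible.
"""

import tempfile
from pathlib import Path

from spastigen.dataset import generate_dataset, verify_dataset

with tempfile.TemporaryDirectory() as tmp:
    root = Path(tmp) / "dataset"
    manifest = generate_dataset(root, patients=[1, 2], seed=42)
    print(f"TRC motion files: {manifest.count('TRC')} (= 2 patients x 4 movements)")
    print(f"STO simulation bundles: {manifest.count('STO')} (= 8 x 6 MAS grades)")
    print(f"config hash: {manifest.config_hash}")
    for sub in sorted(p.relative_to(root) for p in root.rglob("*") if p.is_file())[:6]:
        print(f"  {sub}")
    problems = verify_dataset(manifest, root)
    print(f"verification problems: {len(problems)} (fresh tree is clean)")
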