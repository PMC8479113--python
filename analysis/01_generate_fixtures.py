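"""Generate the synthetic open/closed hexamer fixtures and toy geometries.

Writes multi-model PDBs plus a checksum manifest under results/fixtures/.
The open (deoxygenated-like) state uses counter-rotating trimeric rings,
a larger subunit shell and looser ring packing; the closed (oxygenated-like)
state uses the clam-shell mode with tighter packing and a smaller aperture.
"""

import json

from hexadyn.pipeline import make_fixtures

if __name__ == "__main__":
    manifest = make_fixtures(seed=1, output_dir="results/fixtures")
    print(f"wrote {len(manifest)} fixture files to results/fixtures/")
    print(json.dumps(manifest, indent=2))
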