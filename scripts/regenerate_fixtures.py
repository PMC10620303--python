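"""Rebuild the packaged fixture parameter sets from their seeded searches.

Usage:  python scripts/regenerate_fixtures.py

Writes src/turingcross/data/{admissible,symmetric}_fixture.json and the
matching .meta.json provenance sidecars.  The procedures are fully
deterministic; rerunning reproduces byte-identical files.
"""
from __future__ import annotations

import json
from pathlib import Path

from turingcross.fixtures import (
    generate_admissible_fixture,
    generate_symmetric_fixture,
)

DATA = Path(__file__).resolve().parent.parent / "src" / "turingcross" / "data"


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    for name, generator in (
        ("admissible", generate_admissible_fixture),
        ("symmetric", generate_symmetric_fixture),
    ):
        params, meta = generator()
        params.save(DATA / f"{name}_fixture.json")
        (DATA / f"{name}_fixture.meta.json").write_text(
            json.dumps(meta, indent=2, sort_keys=True) + "\n"
        )
        print(f"{name}: d_used = {params.d:.4g}  ->  {name}_fixture.json")


if __name__ == "__main__":
    main()
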