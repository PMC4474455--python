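"""PCR-duplicate removal by monoclonization.

Sonication breaks chromosomes from different cells at effectively random
positions, so two independent DNA fragments almost never share both end
coordinates.  All read pairs whose resolved fragment ends coincide on the
same chromosome and bisulfite strand are therefore treated as PCR copies of
one original molecule ("clone") and collapsed to the single pair with the
best mapping score.  Coordinate-identical fragments from opposite bisulfite
strands remain distinct clones because methylation is called per strand.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["CLONE_KEY", "monoclonize"]

CLONE_KEY = ["chrom", "frag_start", "frag_end", "fragment_strand"]


def monoclonize(pairs: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Collapse read pairs sharing both fragment-end coordinates.

    Within each clone-key group the pair with the best (lowest) score is
    kept; score ties break deterministically on the lexicographically first
    read identifier.  Returns the deduplicated table plus a summary with
    the input tag count, output clone count, and clone fraction.

    Unresolved rows (null chromosome) are dropped before keying.
    """
    resolved = pairs[pairs["chrom"].notna()].copy()
    n_tags = len(resolved)
    ordered = resolved.sort_values(
        CLONE_KEY + ["score", "read_id"], kind="mergesort"
    )
    clones = ordered.drop_duplicates(subset=CLONE_KEY, keep="first").reset_index(
        drop=True
    )
    summary = {
        "tags": n_tags,
        "clones": len(clones),
        "clone_fraction": len(clones) / n_tags if n_tags else float("nan"),
    }
    return clones, summary
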