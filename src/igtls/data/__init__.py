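"""Packaged reference inputs.

``spontaneous_aberrations.tsv`` holds the spontaneous chromosomal aberration
counts scored over 100 metaphase spreads per line in the DT40 TLS-polymerase
panel (wild-type, single and double polymerase knockouts, and the two
reconstituted double-knockout lines); ``pqts.yaml`` / ``pqto.yaml`` are toy
lesion-plasmid architectures with the original site geometry but arbitrary
flanking sequence.
"""

from importlib import resources

import pandas as pd

from ..countstats import AberrationCount


def _path(name: str):
    return resources.files(__package__) / name


def aberration_counts() -> list[AberrationCount]:
    """The packaged spontaneous aberration counts, one row per cell line."""
    df = pd.read_csv(_path("spontaneous_aberrations.tsv"), sep="\t")
    return [
        AberrationCount(
            label=row["line"],
            n_cells=int(row["n_cells"]),
            chromatid_gaps=int(row["chromatid_gaps"]),
            chromatid_breaks=int(row["chromatid_breaks"]),
            isochromatid_gaps=int(row["isochromatid_gaps"]),
            isochromatid_breaks=int(row["isochromatid_breaks"]),
        )
        for _, row in df.iterrows()
    ]


def architecture(name: str):
    """Load a packaged lesion-plasmid architecture: ``pqts`` or ``pqto``."""
    from ..seq_io import load_architecture

    if name not in ("pqts", "pqto"):
        raise ValueError("architecture name must be 'pqts' or 'pqto'")
    return load_architecture(_path(f"{name}.yaml"))
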