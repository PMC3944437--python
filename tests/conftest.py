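import pandas as pd
import pytest

from xenomatrisome.filtering import PSM_COLUMNS
from xenomatrisome.proteomes import ProteomeEntry


def make_psms(rows):
    """Build a PSM DataFrame from compact row dicts, defaulting the boilerplate."""
    defaults = {
        "sample_id": "A_r1",
        "replicate_id": "r1",
        "fraction_id": "f1",
        "modifications": "",
        "charge": 2,
        "score": 15.0,
        "precursor_intensity": 1e6,
        "good_isotope_quality": True,
        "is_decoy": False,
    }
    full = [{**defaults, **row} for row in rows]
    return pd.DataFrame(full, columns=PSM_COLUMNS)


@pytest.fixture
def toy_proteome_pair():
    """Two ortholog pairs: one with a diverged peptide, one fully conserved.

    Human/mouse TNC-like pair shares the 10-mer GASDFGHWEK and diverges in
    the second peptide; the second pair is identical between species.
    """
    humans = [
        ProteomeEntry("H1", "human", "TNC", "GASDFGHWEKTTTAAAWGDK"),
        ProteomeEntry("H2", "human", "FN1", "MMMWWWCCCKVVVGGGHHHR"),
    ]
    mice = [
        ProteomeEntry("M1", "mouse", "Tnc", "GASDFGHWEKTTTAASWGDK"),
        ProteomeEntry("M2", "mouse", "Fn1", "MMMWWWCCCKVVVGGGHHHR"),
    ]
    return humans, mice
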