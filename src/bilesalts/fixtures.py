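"""Shipped editable fixtures for node-level ancestral inference.

The amniote fixture is a *synthetic* group-level summary tree and character
coding assembled from the comparative literature on vertebrate bile-salt
phenotypes, not a transcription of any published data table: tips are broad
lineages (lobe-finned fish, Mammalia, tuatara, lizards, snakes, Testudines,
Crocodylia, Aves), the topology places Testudines as sister to
Crocodylia+Aves, and each tip is coded for presence/absence of the three
compound types at the 10% pool threshold (plus 24R-hydroxylated C27 acids,
the lepidosaur innovation).  Labelled internal nodes:

* ``nodeA`` — the root (bony-vertebrate ancestor);
* ``nodeB`` — the Testudines/Crocodylia/Aves ancestor, where parsimony
  supports both C27 bile alcohols and C27 bile acids;
* ``nodeC`` — the lepidosaur ancestor (tuatara + squamates).

Both files live under ``bilesalts/data`` and are plain text, meant to be
edited when better codings become available.
"""

from __future__ import annotations

from importlib import resources

import dendropy

from .phylo import CharacterMatrix

__all__ = ["amniote_tree", "amniote_characters"]


def _data(name: str):
    return resources.files("bilesalts.data") / name


def amniote_tree() -> dendropy.Tree:
    text = _data("amniote_tree_synthetic.nwk").read_text()
    return dendropy.Tree.get(data=text, schema="newick",
                             preserve_underscores=True)


def amniote_characters() -> CharacterMatrix:
    from .io import read_character_matrix

    with resources.as_file(_data("amniote_characters_synthetic.csv")) as path:
        return read_character_matrix(path)
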