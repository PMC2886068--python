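#!/usr/bin/env python
"""Classify every surveyed species and screen families for conservation.

Reads results/survey_profiles.csv, assigns the I-VI profile class and the
complexity label per species, tabulates unusual-modification flags, and
writes the within-family conservation screen.  Outputs:
results/survey_classes.csv, results/survey_conservation.csv.
"""

from collections import Counter
from pathlib import Path

import pandas as pd

from bilesalts import io as bio
from bilesalts.compounds import flag_unusual
from bilesalts.phylo import conservation_report
from bilesalts.profiles import assign_class, is_complex, major_minor

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    result = bio.read_profile_table(RESULTS / "survey_profiles.csv")
    assert not result.errors, result.errors
    profiles = result.profiles

    rows = []
    flag_counts: Counter = Counter()
    for p in profiles:
        parts = major_minor(p)
        major = parts.major[0].name if parts.major else ""
        flags = set()
        for c in p.components:
            flags |= flag_unusual(c.descriptor)
        flag_counts.update(f.value for f in flags)
        rows.append({
            "species": p.species,
            "family": p.family,
            "diet": p.diet,
            "profile_class": assign_class(p).value,
            "complex": str(is_complex(p)).lower(),
            "major_bile_salt": major,
            "flags": "|".join(sorted(f.value for f in flags)),
        })
    frame = pd.DataFrame(rows)
    frame.to_csv(RESULTS / "survey_classes.csv", index=False)

    groups = conservation_report(profiles, rank="family")
    bio.write_conservation(groups, RESULTS / "survey_conservation.csv")

    class_counts = frame["profile_class"].value_counts().to_dict()
    n_complex = (frame["complex"] == "true").sum()
    het = [g.group for g in groups if g.heterogeneous]
    print(f"classified {len(profiles)} species: {class_counts}")
    print(f"complex profiles: {n_complex} ({100.0 * n_complex / len(profiles):.1f}%)")
    print(f"modification flags seen: {dict(flag_counts)}")
    print(f"heterogeneous families: {len(het)} of {len(groups)} "
          f"({', '.join(het[:6])}{'...' if len(het) > 6 else ''})")
    print("wrote survey_classes.csv, survey_conservation.csv")


if __name__ == "__main__":
    main()
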