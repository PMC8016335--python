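"""Independent brute-force reference for the panel classifier.

Deliberately naive: plain nested loops over every peak against every mass of
every panel, then the same candidate rules expressed without any of the
package's matching code. Used to cross-check zoomsid.classification.classify.
"""

from zoomsid.reference_panels import SLOT_LABELS, lca


def brute_classify(pl, panels, params):
    """Return (status, sorted candidate names, resolved clade name or None)."""
    peaks = [float(m) for m in pl.mz]

    per_panel = []
    for panel in panels:
        matched_slots = set()
        explained = set()
        for slot in SLOT_LABELS:
            for mass in panel.masses.get(slot, ()):
                for j, mz in enumerate(peaks):
                    if abs(mz - mass) <= params.tolerance:
                        matched_slots.add(slot)
                        explained.add(j)
        defined = sum(1 for s in SLOT_LABELS if panel.masses.get(s))
        coverage = len(matched_slots) / defined if defined else 0.0
        per_panel.append((panel.taxon, matched_slots, explained, coverage))

    qualifiers = [
        (taxon, slots, explained)
        for taxon, slots, explained, coverage in per_panel
        if len(slots) >= params.min_matched and coverage >= params.min_coverage
    ]

    if params.absence_check:
        survivors = []
        for taxon, slots, explained in qualifiers:
            dominated = False
            for taxon2, slots2, explained2 in qualifiers:
                if taxon2 is taxon:
                    continue
                if slots2 >= slots and (explained2 - explained):
                    dominated = True
                    break
            if not dominated:
                survivors.append((taxon, slots, explained))
        qualifiers = survivors

    if not qualifiers:
        return "no_id", [], None
    best = max(len(slots) for _, slots, _ in qualifiers)
    candidates = [taxon for taxon, slots, _ in qualifiers if len(slots) == best]
    return ("identified", sorted(t.name for t in candidates),
            lca(candidates).name)
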