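"""Independent brute-force reference for the pileup -> feature/label path.

Deliberately naive: each alignment is replayed into per-position events, a
placeholder column is literally spliced into a Python list for every
reserved insertion slot, and the 11-field vectors and labels are recomputed
from those spliced columns with fresh code.  Used only to cross-check the
production encoder.
"""

from __future__ import annotations

BASE_FIELDS = "ATGCatgc"


def brute_force_encode(long_read, alignments):
    """Return (features, labels) as plain nested lists."""
    L = len(long_read.sequence)

    # per-alignment events on the original axis
    events = []  # ('match', tpos, base_char_cased) / ('del', tpos) / ('ins', anchor, string_cased)
    for aln in alignments:
        lower = aln.strand == "reverse"
        q = aln.query_sequence
        qp, tp = 0, aln.target_start
        for op, n in aln.cigar:
            if op in "M=X":
                for i in range(n):
                    ch = q[qp + i].upper()
                    events.append(("match", tp + i, ch.lower() if lower else ch))
                qp += n
                tp += n
            elif op == "D":
                for i in range(n):
                    events.append(("del", tp + i))
                tp += n
            elif op == "I":
                ins = q[qp : qp + n]
                ins = ins.lower() if lower else ins.upper()
                events.append(("ins", tp - 1, ins))
                qp += n
            elif op == "S":
                qp += n
            elif op == "N":
                tp += n

    # literal splicing: one dict per slot
    axis = [{"kind": "orig", "pos": p} for p in range(L)]
    reserved = {}
    for kind, *rest in events:
        if kind == "ins":
            anchor, s = rest
            reserved[anchor] = max(reserved.get(anchor, 0), len(s))
    for anchor in sorted(reserved, reverse=True):
        slots = [
            {"kind": "ins", "anchor": anchor, "offset": k}
            for k in range(reserved[anchor])
        ]
        insert_at = next(
            i for i, c in enumerate(axis) if c["kind"] == "orig" and c["pos"] == anchor
        ) + 1 if anchor >= 0 else 0
        axis[insert_at:insert_at] = slots

    for col in axis:
        col.update({b: 0 for b in BASE_FIELDS})
        col.update(dels=0, ncount=0, cov=0)

    by_orig = {c["pos"]: c for c in axis if c["kind"] == "orig"}
    by_ins = {(c["anchor"], c["offset"]): c for c in axis if c["kind"] == "ins"}

    for ev in events:
        if ev[0] == "match":
            col = by_orig[ev[1]]
            col["cov"] += 1
            if ev[2].upper() == "N":
                col["ncount"] += 1
            else:
                col[ev[2]] += 1
        elif ev[0] == "del":
            col = by_orig[ev[1]]
            col["cov"] += 1
            col["dels"] += 1
        else:
            _, anchor, s = ev
            for k, ch in enumerate(s):
                if ch.upper() != "N":
                    by_ins[(anchor, k)][ch] += 1

    # inserted-slot coverage = coverage of the anchor column
    for (anchor, _), col in by_ins.items():
        if anchor >= 0:
            col["cov"] = by_orig[anchor]["cov"]
        else:
            col["cov"] = sum(by_ins[(anchor, 0)][b] for b in BASE_FIELDS)

    features, labels = [], []
    for col in axis:
        base_support = sum(col[b] for b in BASE_FIELDS)
        if col["kind"] == "orig":
            no_base = col["dels"] + col["ncount"]
        else:
            no_base = max(col["cov"] - base_support, 0)
        vec = [0] * 11
        if col["cov"] == 0:
            if col["kind"] == "orig":
                orig = long_read.sequence[col["pos"]]
                if orig in "ATGC":
                    vec[BASE_FIELDS.index(orig)] = 1
            vec[9] = 1
        else:
            for i, b in enumerate(BASE_FIELDS):
                vec[i] = col[b]
            vec[8] = 1 if col["dels"] > 0 else 0
            vec[9] = 1 if no_base > base_support else 0
            vec[10] = 1
        features.append(vec)

        if col["cov"] == 0:
            orig = long_read.sequence[col["pos"]] if col["kind"] == "orig" else None
            labels.append({"A": 0, "T": 1, "G": 2, "C": 3}.get(orig, 4))
        else:
            pooled = [col[b] + col[b.lower()] for b in "ATGC"]
            best = max(range(4), key=lambda i: (pooled[i], -i))
            if no_base > base_support or col["dels"] > pooled[best] or pooled[best] == 0:
                labels.append(4)
            else:
                labels.append(best)
    return features, labels
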