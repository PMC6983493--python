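"""Shared helpers for the test suite."""

from __future__ import annotations

from svmeta.models import SVCall


def mk_call(
    sv_type: str,
    start: int,
    end: int,
    support: int = 10,
    caller: str = "pindel",
    technology: str = "short",
    length: int | None = None,
    call_id: str | None = None,
) -> SVCall:
    if length is None:
        length = end - start + 1 if sv_type != "INS" else 100
    return SVCall(
        id=call_id or f"{caller}_{sv_type}_{start}_{end}",
        caller=caller,
        technology=technology,
        sv_type=sv_type,
        start=start,
        end=end,
        length=length,
        read_support=support,
    )


def naive_ward_partition(points, t):
    """Brute-force agglomerative Ward clustering cut at height ``t``.

    Lance-Williams update on squared distances; merges applied greedily
    while the smallest linkage distance stays within ``t``.  Returns the
    partition as a set of frozensets of point indices.
    """
    n = len(points)
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    d2: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            d2[(i, j)] = float(
                (points[i][0] - points[j][0]) ** 2
                + (points[i][1] - points[j][1]) ** 2
            )
    next_id = n
    while len(clusters) > 1:
        (a, b), best = min(d2.items(), key=lambda kv: (kv[1], kv[0]))
        if best ** 0.5 > t:
            break
        na, nb = len(clusters[a]), len(clusters[b])
        dab = d2.pop((a, b))
        members = clusters.pop(a) + clusters.pop(b)
        for c in list(clusters):
            nc = len(clusters[c])
            dac = d2.pop((min(a, c), max(a, c)))
            dbc = d2.pop((min(b, c), max(b, c)))
            d2[(c, next_id)] = (
                (na + nc) * dac + (nb + nc) * dbc - nc * dab
            ) / (na + nb + nc)
        clusters[next_id] = members
        next_id += 1
    return {frozenset(m) for m in clusters.values()}
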