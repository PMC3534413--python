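from __future__ import annotations

import numpy as np
import pytest

from dtnet.records import COMPLEX, InteractionRecord, Interactome


def mk_rec(rid, interactors, kind="binary", **kw) -> InteractionRecord:
    return InteractionRecord(
        record_id=rid, interactors=tuple(interactors), record_kind=kind, **kw
    )


def random_interactome(rng: np.random.Generator, n_proteins=12, n_records=15) -> Interactome:
    """Small random interactome mixing binary and complex records."""
    proteins = [f"P{i}" for i in range(n_proteins)]
    records = []
    for i in range(n_records):
        if rng.random() < 0.7:
            u, v = rng.choice(n_proteins, 2, replace=False)
            inter, kind = (proteins[u], proteins[v]), "binary"
        else:
            size = int(rng.integers(3, min(6, n_proteins) + 1))
            idx = rng.choice(n_proteins, size, replace=False)
            inter, kind = tuple(proteins[j] for j in idx), COMPLEX
        records.append(
            InteractionRecord(
                record_id=f"r{i}",
                interactors=inter,
                record_kind=kind,
                hub_index=0 if kind == COMPLEX else None,
                source_db=["dbA", "dbB"][int(rng.integers(2))],
                pmid=f"pmid:{int(rng.integers(5))}",
                detection_method=["m_binary", "m_nary"][int(rng.integers(2))],
                mi_intact=None if rng.random() < 0.3 else round(float(rng.random()), 3),
                mi_psicquic=None if rng.random() < 0.3 else round(float(rng.random()), 3),
                predicted=bool(rng.random() < 0.2),
            )
        )
    return Interactome(records)


def random_adjacency(rng: np.random.Generator, n: int, p: float = 0.2) -> dict:
    """Random simple graph as an adjacency dict (possibly disconnected)."""
    adj = {i: set() for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                adj[i].add(j)
                adj[j].add(i)
    return adj


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
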