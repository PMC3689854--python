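"""Deterministic work distribution.

Results are returned in input order whatever the worker count, so any
pipeline stage mapped through here is byte-identical for 1 or N workers.
Parallelism is applied where the workload is embarrassingly parallel: the
per-reference overlap/assembly stage and the all-pairs duplex alignment.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence, TypeVar

T = TypeVar("T")
R = TypeVar("R")


def parallel_map(fn: Callable[[T], R], items: Iterable[T], workers: int = 1) -> list[R]:
    """Apply ``fn`` over ``items``; results in input order.

    ``workers=1`` runs in-process; more workers dispatch through joblib.
    A failing item propagates with its identity attached.
    """
    if workers < 1:
        raise ValueError("workers must be >= 1")
    items = list(items)
    if workers == 1 or len(items) <= 1:
        return [_guarded(fn, x) for x in items]
    from joblib import Parallel, delayed

    return Parallel(n_jobs=workers)(delayed(_guarded)(fn, x) for x in items)


def _guarded(fn: Callable[[T], R], item: T) -> R:
    try:
        return fn(item)
    except Exception as exc:
        raise RuntimeError(f"worker failed on item {item!r}: {exc}") from exc
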