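"""Dataset preparation: flip/mirror augmentation, class balancing, splitting.

The classification stage downstream needs a balanced two-class pool
(calculus / no-calculus) split into training, testing and validation sets.
The operations here are metadata-first: a :class:`LabeledItem` records the
label, the geometric transform applied (if any) and the originating item,
so augmented copies can be traced — and kept in the same split subset as
their source to avoid train/test leakage.

Split arithmetic: with pool size N, a holdout fraction h and a training
fraction t of the remainder,

    rest  = floor(N * (1 - h))        (training + testing pool)
    train = floor(rest * t)
    test  = rest - train
    validation = N - rest

Floors on the two products, remainders cascading to test then validation —
e.g. N=1340, h=0.2, t=0.7 gives 750 / 322 / 268.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError

__all__ = [
    "TRANSFORMS",
    "LabeledItem",
    "SplitResult",
    "apply_transform",
    "augment_flip_mirror",
    "balance_classes",
    "split_two_stage",
]

TRANSFORMS = ("hflip", "vflip", "hvflip")


@dataclass(frozen=True)
class LabeledItem:
    """One pooled image with its label and augmentation provenance."""

    id: str
    label: str  # "calculus" | "no_calculus"
    transform_tag: str = "none"
    source_id: str | None = None

    def __post_init__(self):
        if self.transform_tag not in ("none", *TRANSFORMS):
            raise ParameterError(f"unknown transform_tag {self.transform_tag!r}")

    @property
    def root_id(self) -> str:
        """The originating item's id (itself when not augmented)."""
        return self.source_id if self.source_id is not None else self.id


@dataclass
class SplitResult:
    train: list[str]
    test: list[str]
    validation: list[str]

    def counts(self) -> tuple[int, int, int]:
        return len(self.train), len(self.test), len(self.validation)


def apply_transform(image: np.ndarray, tag: str) -> np.ndarray:
    """Apply a recorded flip/mirror tag; each transform is an involution."""
    if tag == "none":
        return image.copy()
    if tag == "hflip":
        return image[:, ::-1].copy()
    if tag == "vflip":
        return image[::-1, :].copy()
    if tag == "hvflip":
        return image[::-1, ::-1].copy()
    raise ParameterError(f"unknown transform tag {tag!r}")


def augment_flip_mirror(item: LabeledItem, image: np.ndarray,
                        seed: int | np.random.Generator,
                        new_id: str | None = None) -> tuple[LabeledItem, np.ndarray]:
    """Create one augmented copy with a uniformly chosen flip/mirror.

    The chosen transform is recorded in ``transform_tag`` and the new item
    points back at its source; applying the same transform twice restores
    the original raster.
    """
    if np.asarray(image).size == 0:
        raise ParameterError("cannot augment an empty image")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tag = str(rng.choice(TRANSFORMS))
    out = apply_transform(np.asarray(image), tag)
    new = LabeledItem(
        id=new_id if new_id is not None else f"{item.id}~{tag}",
        label=item.label,
        transform_tag=tag,
        source_id=item.root_id,
    )
    return new, out


def balance_classes(pool: list[LabeledItem], target: int | None = None,
                    seed: int = 0) -> list[LabeledItem]:
    """Equalize the two classes at ``target`` items each.

    The minority class is topped up with flip/mirror-augmented copies of
    uniformly re-sampled sources (with replacement); the majority class is
    subsampled without replacement.  Default target is floor(total / 2), so
    a 428 / 912 pool balances to 670 / 670.
    """
    labels = sorted({it.label for it in pool})
    if len(labels) != 2:
        raise ParameterError(f"balancing expects exactly two classes, got {labels}")
    by_label = {lab: [it for it in pool if it.label == lab] for lab in labels}
    if target is None:
        target = len(pool) // 2
    if target < 1:
        raise ParameterError(f"target must be >= 1, got {target}")
    minority = min(by_label.values(), key=len)
    if target < len(minority):
        raise ParameterError(
            f"target {target} is below the minority class count {len(minority)}; "
            "no subsampling rule is defined for the minority class"
        )
    rng = np.random.default_rng(seed)
    out: list[LabeledItem] = []
    for lab in labels:
        items = by_label[lab]
        if len(items) >= target:
            idx = rng.choice(len(items), size=target, replace=False)
            out.extend(items[i] for i in sorted(idx))
        else:
            out.extend(items)
            sources = rng.choice(len(items), size=target - len(items), replace=True)
            tags = rng.choice(TRANSFORMS, size=target - len(items))
            for k, (si, tag) in enumerate(zip(sources, tags)):
                src = items[si]
                out.append(LabeledItem(
                    id=f"{src.id}~aug{k}",
                    label=lab,
                    transform_tag=str(tag),
                    source_id=src.root_id,
                ))
    return out


def split_two_stage(pool: list[LabeledItem] | list[str], holdout_fraction: float,
                    train_fraction_of_rest: float, seed: int = 0) -> SplitResult:
    """Seeded two-stage split into train / test / validation.

    ``holdout_fraction`` is reserved for validation; the remainder is split
    train : test by ``train_fraction_of_rest`` (floors + cascading
    remainders, see module docstring).  ``train_fraction_of_rest = 1`` is
    the degenerate two-way path (empty test set).

    Augmented items are confined to the same subset as their source: items
    sharing a root id move as one group.  With singleton groups the subset
    sizes match the arithmetic exactly; larger groups may shift a boundary
    by at most the group size minus one.
    """
    if not 0.0 < holdout_fraction < 1.0:
        raise ParameterError(f"holdout_fraction must lie in (0, 1), got {holdout_fraction}")
    if not 0.0 < train_fraction_of_rest <= 1.0:
        raise ParameterError(f"train_fraction_of_rest must lie in (0, 1], got {train_fraction_of_rest}")
    items = [it if isinstance(it, LabeledItem) else LabeledItem(id=str(it), label="calculus")
             for it in pool]
    ids = [it.id for it in items]
    if len(set(ids)) != len(ids):
        raise ParameterError("pool ids must be unique")
    n = len(items)
    eps = 1e-9
    rest = math.floor(n * (1.0 - holdout_fraction) + eps)
    n_train = math.floor(rest * train_fraction_of_rest + eps)
    n_test = rest - n_train
    n_val = n - rest
    degenerate = train_fraction_of_rest == 1.0
    if n_train < 1 or n_val < 1 or (n_test < 1 and not degenerate):
        raise ParameterError(
            f"pool of {n} is too small for a {holdout_fraction}/{train_fraction_of_rest} split "
            f"({n_train}/{n_test}/{n_val})"
        )

    groups: dict[str, list[str]] = {}
    for it in items:
        groups.setdefault(it.root_id, []).append(it.id)
    keys = sorted(groups)
    rng = np.random.default_rng(seed)
    rng.shuffle(keys)

    quotas = [n_train, n_test, n_val]
    subsets: list[list[str]] = [[], [], []]
    for key in keys:
        members = groups[key]
        # first subset with room for the whole group; else the least-full one
        remaining = [q - len(s) for q, s in zip(quotas, subsets)]
        fits = [i for i, r in enumerate(remaining) if r >= len(members)]
        dest = fits[0] if fits else int(np.argmax(remaining))
        subsets[dest].extend(members)
    return SplitResult(train=subsets[0], test=subsets[1], validation=subsets[2])
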