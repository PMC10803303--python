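"""Centre-wise cohort splitting: external centres are wholly unseen."""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["SplitPlan", "centre_split"]


@dataclass(frozen=True)
class SplitPlan:
    train_centres: frozenset[str]
    internal_val_centres: frozenset[str]
    external_centres: frozenset[str]

    def __init__(self, train_centres, internal_val_centres, external_centres):
        object.__setattr__(self, "train_centres", frozenset(train_centres))
        object.__setattr__(self, "internal_val_centres", frozenset(internal_val_centres))
        object.__setattr__(self, "external_centres", frozenset(external_centres))
        sets = [self.train_centres, self.internal_val_centres, self.external_centres]
        if any(not s for s in sets):
            raise ValueError("every split must contain at least one centre")
        union = sets[0] | sets[1] | sets[2]
        if len(union) != sum(len(s) for s in sets):
            raise ValueError("splits must be pairwise disjoint")

    @property
    def all_centres(self) -> frozenset[str]:
        return self.train_centres | self.internal_val_centres | self.external_centres

    @property
    def development_centres(self) -> frozenset[str]:
        return self.train_centres | self.internal_val_centres


def centre_split(cohort, plan: SplitPlan):
    """Partition cases purely by centre_id into (train, internal, external)."""
    cohort_centres = {c.centre_id for c in cohort}
    unknown = plan.all_centres - cohort_centres
    if unknown:
        raise ValueError(f"plan references centres absent from cohort: {sorted(unknown)}")
    uncovered = cohort_centres - plan.all_centres
    if uncovered:
        raise ValueError(f"cohort centres not covered by plan: {sorted(uncovered)}")
    train = [c for c in cohort if c.centre_id in plan.train_centres]
    internal = [c for c in cohort if c.centre_id in plan.internal_val_centres]
    external = [c for c in cohort if c.centre_id in plan.external_centres]
    return train, internal, external
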