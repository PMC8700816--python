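"""Build an I-efficient mixture design from a candidate lattice.

Constructs candidate blends on a three-component lattice, selects 12
runs by point exchange to minimize the average scaled prediction variance
(the I-optimality criterion) for a reduced-cubic model, and augments with
5 replicate runs so the design supports a lack-of-fit test — the same
17-run / 5-pure-error-df structure as the bundled study.
"""

from mixsurf import (
    augment_replicates,
    candidate_set,
    coordinate_exchange,
    i_criterion,
    scheffe_terms,
)

cands = candidate_set(3, [0, 1 / 3, 1 / 2, 2 / 3, 1])
terms = scheffe_terms(3, "reduced_cubic")
print(f"{len(cands.blends)} candidate blends (lattice + centroid + axial points)")

base = coordinate_exchange(cands, n_runs=12, terms=terms, n_starts=5, seed=0)
print(f"12-run exchange design: I-criterion = {i_criterion(base, terms):.4f}")

design = augment_replicates(base, 17, terms)
print(
    f"after replicate augmentation: {design.n_runs} runs, "
    f"{design.n_distinct} distinct blends, pure-error df = {design.pure_error_df}"
)
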