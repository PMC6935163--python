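"""Pedigree relatedness: the numerator relationship matrix A, inbreeding, and
the status-number effective population size.

Builds a tiny three-generation pedigree, orders it, and prints A (twice the
coancestry matrix), per-individual inbreeding F = a_ii - 1, and the status
number Ns = 0.5 / (group coancestry) of the youngest generation.
"""

from pinegs import Pedigree, build_A, inbreeding, sort_pedigree, status_number

ped = sort_pedigree(
    Pedigree(
        [
            ("gp1", "0", "0"),
            ("gp2", "0", "0"),
            ("sire", "gp1", "gp2"),
            ("dam", "gp1", "gp2"),       # full sib of 'sire'
            ("kid1", "sire", "dam"),     # full-sib mating -> F = 0.25
            ("kid2", "sire", "dam"),
        ]
    )
)

A = build_A(ped)
print("numerator relationship matrix A:")
print(A.round(3).to_string())
print()
print("inbreeding coefficients (a_ii - 1):")
print(inbreeding(A).round(3).to_string())
print()
ns = status_number(ped, ["kid1", "kid2"], A=A)
print(f"status number of the progeny group: Ns = {ns:.3f}")
print(
    "\nkid1/kid2 are progeny of a full-sib mating, so F = 0.25 and their\n"
    "relationship a = 1.25 exceeds the full-sib 0.5; Ns well below 2 reflects\n"
    "the accumulated coancestry of the group."
)
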