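#!/usr/bin/env python
"""Subdomain and dimer geometry on synthetic assemblies of known truth.

Builds a kinked two-subdomain domain (16.3°, 8+8 repeats — the NLRC4-like
configuration) and two-fold dimers at the TLR3-like (L = 74.5 Å,
ψ = 148°) and TLR1/2-like (L = 44.0 Å, ψ = 168°) arrangements, with
0.2 Å positional noise, and measures how well Ω, L and ψ are recovered.
Writes results/assembly_geometry.tsv.

Note the kinked-domain angle: with only eight reference points per
subdomain the fitted axes scatter by several degrees at this noise level,
and the angle between two noisy axis estimates is biased upward — the
mean recovered Ω sits above the true 16.3° (see docs/methods.md).
"""

import dataclasses
from pathlib import Path

import numpy as np

from lrrgeom.assembly import detect_subdomains, dimer_geometry
from lrrgeom.simulate import DimerSpec, HelixSpec, make_dimer, make_kinked_domain

ROOT = Path(__file__).resolve().parent.parent
N_REP = 64


def main() -> None:
    rows = ["configuration\tquantity\ttruth\trecovered_mean\trecovered_sd\tn"]

    spec = HelixSpec(P=33.0, R=15.0, N=20.0, n=8, noise_sd=0.2)
    clean = dataclasses.replace(spec, noise_sd=0.0)
    omegas = []
    for seed in range(N_REP):
        pts, truth = make_kinked_domain(
            dataclasses.replace(spec, seed=seed), clean, 16.3
        )
        split = detect_subdomains(pts, split_points=(truth["split_start"],))
        omegas.append(split.omega[0])
    rows.append(
        f"kink_nlrc4_like\tomega_deg\t16.3\t{np.mean(omegas):.2f}\t"
        f"{np.std(omegas):.2f}\t{N_REP}"
    )
    print(f"kinked domain (truth 16.3°): recovered Ω = "
          f"{np.mean(omegas):.2f} ± {np.std(omegas):.2f}°")

    for tag, monomer, L, psi in [
        ("dimer_tlr3_like", HelixSpec(P=5.0, R=23.0, N=32.0, n=25, noise_sd=0.2), 74.5, 148.0),
        ("dimer_tlr12_like", HelixSpec(P=-30.0, R=22.5, N=28.7, n=20, noise_sd=0.2), 44.0, 168.0),
    ]:
        Ls, psis = [], []
        for seed in range(N_REP):
            a, b, _ = make_dimer(DimerSpec(monomer=monomer, L_true=L, psi_true=psi, seed=seed))
            g = dimer_geometry(a, b)
            Ls.append(g.L)
            psis.append(g.psi)
        rows.append(f"{tag}\tL_angstrom\t{L}\t{np.mean(Ls):.2f}\t{np.std(Ls):.2f}\t{N_REP}")
        rows.append(f"{tag}\tpsi_deg\t{psi}\t{np.mean(psis):.2f}\t{np.std(psis):.2f}\t{N_REP}")
        print(f"{tag} (truth L={L} Å, ψ={psi}°): recovered "
              f"L = {np.mean(Ls):.2f} ± {np.std(Ls):.2f} Å, "
              f"ψ = {np.mean(psis):.2f} ± {np.std(psis):.2f}°")

    out = ROOT / "results" / "assembly_geometry.tsv"
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text("\n".join(rows) + "\n")
    print(f"\n-> {out}")


if __name__ == "__main__":
    main()
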