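"""Simulate the three reference infusions into the baseline eye.

Builds the porcine corneoscleral geometry, meshes it, and infuses 15 uL at
15 / 1 / 0.1 uL/s with baseline viscoelastic materials.  Prints the
end-of-infusion IOP elevation per rate -- faster infusions give the shell
less time to relax, hence higher pressures -- and writes the fast-rate time
series (CSV) and final field snapshot (legacy VTK) under scratch/.
"""

from pathlib import Path

from iopsim import (
    BASELINE_GEOMETRY,
    CORNEA_BASELINE,
    FAST,
    INTERMEDIATE,
    SCLERA_BASELINE,
    SLOW,
    build_geometry,
    compute_fields,
    enclosed_volume,
    generate_mesh,
    simulate_infusion,
)
from iopsim.io import write_timeseries_csv, write_vtk

out = Path("scratch")
out.mkdir(exist_ok=True)

mesh = generate_mesh(build_geometry(BASELINE_GEOMETRY), target_element_size=0.25)
print(f"mesh: {mesh.n_elements} quadratic triangles, cavity volume {enclosed_volume(mesh):.0f} uL")

for protocol in (FAST, INTERMEDIATE, SLOW):
    res = simulate_infusion(mesh, CORNEA_BASELINE, SCLERA_BASELINE, protocol)
    print(
        f"{protocol.name:>12s}: {protocol.rate:5.1f} uL/s x {protocol.duration:5.0f} s "
        f"-> dIOP(15 uL) = {res.final_diop:5.2f} mmHg "
        f"(absolute IOP {res.iop_mmhg[-1]:5.2f} mmHg)"
    )
    if protocol is FAST:
        write_timeseries_csv(out / "fast_infusion.csv", res)
        fields = compute_fields(res, float(res.time[-1]))
        write_vtk(
            out / "fast_final_fields.vtk",
            mesh,
            point_data={"displacement": fields["displacement"]},
            cell_data={
                "von_mises_MPa": fields["von_mises_MPa"],
                "principal_strain_1": fields["principal_strain_1"],
            },
        )

print(f"wrote {out / 'fast_infusion.csv'} and {out / 'fast_final_fields.vtk'}")
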