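"""Plain-text trajectory and stress I/O: GROMACS-energy-style .xvg and .gro.

The .xvg dialect: whitespace-separated columns, ``#`` comment lines, ``@``
plot directives (ignored on read); column order time, P_xx, P_yy, P_zz,
P_xy, P_xz, P_yz by default (configurable).  Box volume and temperature are
carried in ``#`` comments so a write/read round trip is lossless.

The .gro frames use the fixed-column coordinate layout (residue number =
molecule id, atom name = element symbol, positions in nm, final box line);
multiple frames are concatenated.
"""

from __future__ import annotations

import re

import numpy as np

from .constants import ATOMIC_MASSES
from .frames import TrajectoryFrames
from .stress import COMPONENT_ORDER, StressSeries

XVG_DEFAULT_COLUMNS = ("xx", "yy", "zz", "xy", "xz", "yz")


def write_xvg_stress(
    series: StressSeries,
    path,
    columns: tuple = XVG_DEFAULT_COLUMNS,
    comments: bool = True,
) -> None:
    with open(path, "w") as fh:
        if comments:
            fh.write("# dendrorelax pressure-tensor series\n")
            fh.write(f"# volume_nm3 = {series.volume!r}\n")
            fh.write(f"# temperature_K = {series.temperature!r}\n")
            fh.write('@    title "Pressure tensor"\n')
            fh.write('@    xaxis  label "Time (ps)"\n')
            for i, name in enumerate(columns):
                fh.write(f'@ s{i} legend "Pres-{name.upper()} (bar)"\n')
        t = np.arange(series.n_frames) * series.dt
        data = np.column_stack(
            [t] + [series.column(name) for name in columns]
        )
        np.savetxt(fh, data, fmt="%14.6f")


def read_xvg_stress(
    path,
    volume: float | None = None,
    temperature: float | None = None,
    columns: tuple = XVG_DEFAULT_COLUMNS,
) -> StressSeries:
    """Parse a columnar .xvg pressure-tensor file.

    ``volume``/``temperature`` override values found in ``#`` comments; one
    of the two sources must provide each.
    """
    rows, times = [], []
    n_expected = 1 + len(columns)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("@"):
                continue
            if s.startswith("#"):
                m = re.match(r"#\s*(volume_nm3|temperature_K)\s*=\s*([0-9.eE+-]+)", s)
                if m:
                    if m.group(1) == "volume_nm3" and volume is None:
                        volume = float(m.group(2))
                    elif m.group(1) == "temperature_K" and temperature is None:
                        temperature = float(m.group(2))
                continue
            parts = s.split()
            if len(parts) != n_expected:
                missing = n_expected - len(parts)
                raise ValueError(
                    f"{path}:{lineno}: expected {n_expected} columns "
                    f"(time + {', '.join(columns)}), got {len(parts)}"
                    + (f" — {missing} tensor column(s) missing" if missing > 0 else "")
                )
            try:
                vals = [float(p) for p in parts]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable number: {exc}") from None
            times.append(vals[0])
            rows.append(vals[1:])
    if len(rows) < 2:
        raise ValueError(f"{path}: need at least 2 data rows")
    times = np.asarray(times)
    dts = np.diff(times)
    if np.any(dts <= 0):
        bad = int(np.argmax(dts <= 0)) + 2
        raise ValueError(f"{path}: non-monotonic time at data row {bad}")
    data = np.asarray(rows)
    comp = np.empty_like(data)
    for i, name in enumerate(columns):
        comp[:, COMPONENT_ORDER.index(name)] = data[:, i]
    if volume is None or temperature is None:
        raise ValueError(
            f"{path}: volume/temperature not found in comments and not supplied"
        )
    return StressSeries(
        dt=float(np.median(dts)), components=comp, volume=volume, temperature=temperature
    )


def write_gro_frames(frames: TrajectoryFrames, path, wrap: bool = False) -> None:
    fr = frames.wrapped() if wrap else frames
    with open(path, "w") as fh:
        for k in range(fr.n_frames):
            fh.write(f"dendrorelax frame t= {k * fr.dt:.4f} ps\n")
            fh.write(f"{fr.n_beads:5d}\n")
            for i in range(fr.n_beads):
                resid = int(fr.molecule_id[i]) + 1
                x, y, z = fr.coords[k, i]
                fh.write(
                    f"{resid % 100000:5d}{'DND':<5s}{fr.elements[i]:>5s}"
                    f"{(i + 1) % 100000:5d}{x:8.3f}{y:8.3f}{z:8.3f}\n"
                )
            bx, by, bz = fr.box[k]
            fh.write(f"{bx:10.5f}{by:10.5f}{bz:10.5f}\n")


def read_gro_frames(path, dt: float | None = None) -> TrajectoryFrames:
    """Read (possibly concatenated) .gro frames written by write_gro_frames."""
    frames_coords, boxes, times = [], [], []
    elements, mol_id = None, None
    with open(path) as fh:
        lines = fh.readlines()
    pos, lineno = 0, 0
    while pos < len(lines):
        title = lines[pos].rstrip("\n")
        m = re.search(r"t=\s*([0-9.eE+-]+)", title)
        if m:
            times.append(float(m.group(1)))
        try:
            natoms = int(lines[pos + 1])
        except (IndexError, ValueError):
            raise ValueError(
                f"{path}:{pos + 2}: unparseable frame header (atom count expected)"
            ) from None
        body = lines[pos + 2 : pos + 2 + natoms]
        if len(body) < natoms:
            raise ValueError(f"{path}:{pos + 2}: truncated frame ({natoms} atoms expected)")
        coords = np.empty((natoms, 3))
        frame_elements, frame_mol = [], []
        for i, line in enumerate(body):
            lineno = pos + 3 + i
            try:
                resid = int(line[0:5])
                atom_name = line[10:15].strip()
                coords[i, 0] = float(line[20:28])
                coords[i, 1] = float(line[28:36])
                coords[i, 2] = float(line[36:44])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: malformed atom line") from None
            frame_elements.append(atom_name)
            frame_mol.append(resid - 1)
        box_line = lines[pos + 2 + natoms].split()
        if len(box_line) < 3:
            raise ValueError(f"{path}:{pos + 3 + natoms}: malformed box line")
        boxes.append([float(v) for v in box_line[:3]])
        frames_coords.append(coords)
        if elements is None:
            elements, mol_id = frame_elements, frame_mol
        pos += natoms + 3
    if dt is None:
        dt = times[1] - times[0] if len(times) > 1 else 1.0
    masses = np.array(
        [ATOMIC_MASSES.get(re.sub(r"\d", "", e), 1.0) for e in elements]
    )
    return TrajectoryFrames(
        coords=np.array(frames_coords),
        molecule_id=np.array(mol_id),
        elements=elements,
        masses=masses,
        box=np.array(boxes),
        dt=float(dt),
    )


def write_curve_tsv(curve, path, label: str = "G") -> None:
    """Two/three-column TSV (time, value, count) with provenance comments."""
    with open(path, "w") as fh:
        fh.write("# dendrorelax curve\n")
        for k, v in curve.provenance.items():
            fh.write(f"# {k} = {v!r}\n")
        fh.write(f"# normalized = {curve.normalized}\n")
        fh.write(f"time_ps\t{label}\tcount\n")
        for t, g, c in zip(curve.times, curve.values, curve.counts):
            fh.write(f"{t:.8g}\t{g:.8g}\t{c:.8g}\n")


def read_curve_tsv(path):
    """Read a curve written by write_curve_tsv."""
    from .curves import RelaxationModulus

    normalized = False
    rows = []
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if s.startswith("#"):
                if s.startswith("# normalized"):
                    normalized = s.endswith("True")
                continue
            if not s or s[0].isalpha():
                continue
            parts = s.split("\t")
            rows.append([float(p) for p in parts])
    data = np.array(rows)
    counts = data[:, 2] if data.shape[1] > 2 else None
    return RelaxationModulus(data[:, 0], data[:, 1], counts=counts, normalized=normalized)
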