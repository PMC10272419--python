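"""CSV readers/writers for medium and EAC spectra.

Round-trips are lossless: floats are written with shortest-exact ``repr``
precision (17 significant digits where needed), so a write-then-read
reproduces arrays bit for bit.  Dialect: comma separator, dot decimal,
UTF-8, one header row.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .media import MediumSpectrum
from .pipeline import EACSpectrum

__all__ = [
    "FormatError",
    "write_medium_csv",
    "read_medium_csv",
    "write_eac_csv",
    "read_eac_csv",
]

_MEDIUM_COLS = ["wavelength_nm", "n_ex", "n_in", "mu_a", "mu_s_prime", "g", "mu_s"]
_EAC_COLS = ["wavelength_nm", "delta_mu_eff"]


class FormatError(ValueError):
    """A spectrum CSV has the wrong column set or unparsable rows."""


def _write_df(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).write_text(
        ",".join(df.columns)
        + "\n"
        + "\n".join(
            ",".join(repr(float(v)) for v in row) for row in df.to_numpy()
        )
        + ("\n" if len(df) else "")
    )


def _read_df(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: unreadable CSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}; found {list(df.columns)}")
    bad = df[required].isna().any(axis=1)
    if bad.any():
        rows = (np.nonzero(bad.to_numpy())[0] + 2).tolist()  # 1-based + header
        raise FormatError(f"{path}: unparsable values at lines {rows}")
    return df


def write_medium_csv(medium: MediumSpectrum, path: str | Path) -> None:
    _write_df(medium.to_dataframe()[_MEDIUM_COLS], path)


def read_medium_csv(path: str | Path) -> MediumSpectrum:
    df = _read_df(path, _MEDIUM_COLS)
    return MediumSpectrum(
        wavelengths_nm=df["wavelength_nm"].to_numpy(),
        n_ex=df["n_ex"].to_numpy(),
        n_in=df["n_in"].to_numpy(),
        mu_a=df["mu_a"].to_numpy(),
        mu_s_prime=df["mu_s_prime"].to_numpy(),
        g=df["g"].to_numpy(),
        scatterer=None,
    )


def write_eac_csv(spectrum: EACSpectrum, path: str | Path) -> None:
    """EAC spectrum table with run metadata in ``# key=value`` header lines."""
    meta = (
        f"# kind={spectrum.kind} amount={spectrum.amount!r} mask={spectrum.mask} "
        f"engine={spectrum.engine} sds_near_cm={spectrum.sds_pair_cm[0]!r} "
        f"sds_far_cm={spectrum.sds_pair_cm[1]!r}\n"
    )
    df = pd.DataFrame(
        {
            "wavelength_nm": spectrum.wavelengths_nm,
            "delta_mu_eff": spectrum.delta_mu_eff,
        }
    )
    if spectrum.stderr is not None:
        df["stderr"] = spectrum.stderr
    body = (
        ",".join(df.columns)
        + "\n"
        + "\n".join(",".join(repr(float(v)) for v in row) for row in df.to_numpy())
        + ("\n" if len(df) else "")
    )
    Path(path).write_text(meta + body)


def read_eac_csv(path: str | Path) -> EACSpectrum:
    path = Path(path)
    lines = path.read_text().splitlines()
    meta: dict[str, str] = {}
    if lines and lines[0].startswith("#"):
        for token in lines[0][1:].split():
            key, _, value = token.partition("=")
            meta[key] = value
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except Exception as exc:  # pragma: no cover
        raise FormatError(f"{path}: unreadable CSV ({exc})") from exc
    missing = [c for c in _EAC_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}; found {list(df.columns)}")
    return EACSpectrum(
        kind=meta.get("kind", "unknown"),
        amount=float(meta.get("amount", "nan")),
        mask=meta.get("mask", "both"),  # type: ignore[arg-type]
        engine=meta.get("engine", "unknown"),
        sds_pair_cm=(
            float(meta.get("sds_near_cm", "nan")),
            float(meta.get("sds_far_cm", "nan")),
        ),
        wavelengths_nm=df["wavelength_nm"].to_numpy(),
        delta_mu_eff=df["delta_mu_eff"].to_numpy(),
        stderr=df["stderr"].to_numpy() if "stderr" in df.columns else None,
    )
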