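"""Report writing: size estimates as TSV + mirrored JSON."""

from __future__ import annotations

import json

SCHEMA_VERSION = "1.0"

COLUMNS = [
    "locus", "chrom", "start", "end", "motif", "method", "haplotype",
    "n_irr_pairs", "n_irr_anchors", "i", "d", "n_left", "n_right", "ji",
    "n_retained", "f_final", "size_bp", "size_bp_low", "size_bp_high",
    "repeat_copies", "repeat_copies_low", "repeat_copies_high",
]


def estimate_record(locus, estimate) -> dict:
    """Flatten a :class:`~linkstr.irr.SizeEstimate` for one locus into a
    report row."""
    extra = estimate.extra or {}
    profile = extra.get("profile")
    return {
        "locus": locus.name or locus.region,
        "chrom": locus.chrom,
        "start": locus.start,
        "end": locus.end,
        "motif": locus.motif,
        "method": estimate.method,
        "haplotype": estimate.haplotype if estimate.haplotype is not None else "all",
        "n_irr_pairs": extra.get("n_irr_pairs"),
        "n_irr_anchors": extra.get("n_irr_anchors"),
        "i": extra.get("i"),
        "d": extra.get("d"),
        "n_left": profile[0] if profile else None,
        "n_right": profile[1] if profile else None,
        "ji": profile[2] if profile else None,
        "n_retained": extra.get("n_retained"),
        "f_final": extra.get("f_final"),
        "size_bp": estimate.size_bp,
        "size_bp_low": estimate.lower_bp,
        "size_bp_high": estimate.upper_bp,
        "repeat_copies": estimate.repeat_count_estimate,
        "repeat_copies_low": estimate.lower,
        "repeat_copies_high": estimate.upper,
    }


def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def write_report(records: list[dict], path: str) -> tuple[str, str]:
    """Write report rows to ``path`` (TSV) and ``path`` with a ``.json``
    suffix (one object per row, schema-versioned).  Returns both paths."""
    tsv_path = path
    json_path = path + ".json" if not path.endswith(".tsv") else path[:-4] + ".json"
    with open(tsv_path, "w") as fh:
        fh.write("\t".join(COLUMNS) + "\n")
        for rec in records:
            fh.write("\t".join(_fmt(rec.get(c)) for c in COLUMNS) + "\n")
    with open(json_path, "w") as fh:
        json.dump({"schema_version": SCHEMA_VERSION,
                   "records": [{c: rec.get(c) for c in COLUMNS} for rec in records]},
                  fh, indent=1)
        fh.write("\n")
    return tsv_path, json_path


def read_report_tsv(path: str) -> list[dict]:
    """Parse a report TSV back into records (NA -> None, numerics restored)."""
    records: list[dict] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            vals = line.rstrip("\n").split("\t")
            rec: dict = {}
            for col, val in zip(header, vals):
                if val == "NA":
                    rec[col] = None
                else:
                    try:
                        num = float(val)
                        rec[col] = int(num) if num.is_integer() and "." not in val else num
                    except ValueError:
                        rec[col] = val
            records.append(rec)
    return records
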