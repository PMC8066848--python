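"""Brute-force reference for the QC pipeline, written independently of the
package internals: filter -> composite sort -> optional range re-rank ->
slice, in one function over plain record objects."""


def _tax(d):
    return 0 if not d else sum(1 for f in d.split(";") if f.strip())


def qc_oracle(records, cfg):
    keep = [r for r in records
            if (cfg.evalue_max is None or r.evalue <= cfg.evalue_max)
            and (cfg.bitscore_min is None or r.bitscore >= cfg.bitscore_min)
            and (cfg.pident_min is None or
                 (r.pident is not None and r.pident >= cfg.pident_min))
            and (cfg.taxid_min is None or
                 (r.hit_def is not None and _tax(r.hit_def) >= cfg.taxid_min))]
    prim = {"evalue": lambda r: r.evalue,
            "bitscore": lambda r: -r.bitscore,
            "pident": lambda r: -(r.pident if r.pident is not None else 0.0),
            "definition": lambda r: -_tax(r.hit_def)}[cfg.order_key]
    comp = lambda r: (prim(r), r.evalue, -r.bitscore,
                      -(r.pident if r.pident is not None else 0.0), r.source_rank)
    keep.sort(key=comp)
    delta = next((d for d in (cfg.evalue_range, cfg.bitscore_range,
                              cfg.pident_range) if d is not None), None)
    if delta is not None and keep:
        metric = {"evalue": lambda r: r.evalue, "bitscore": lambda r: r.bitscore,
                  "pident": lambda r: r.pident or 0.0}[cfg.order_key]
        best = metric(keep[0])
        ok = ((lambda r: metric(r) <= best + delta) if cfg.order_key == "evalue"
              else (lambda r: metric(r) >= best - delta))
        inside = sorted((r for r in keep if ok(r)),
                        key=lambda r: (-_tax(r.hit_def),) + comp(r))
        keep = inside + [r for r in keep if not ok(r)]
    return keep if cfg.n_hits is None else keep[:cfg.n_hits]
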