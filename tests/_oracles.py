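"""Independent reference implementations used to cross-check the query
engine.  Kept deliberately separate from the package: the oracle answers
conjunctive queries by recursive substitute-and-scan over the statement
list, never by the package's join machinery."""

import re

from glycopath.query import QuerySpec, is_variable
from glycopath.rdf_graph import Literal, TripleGraph


def _ground(term, binding):
    return binding.get(term, term) if is_variable(term) else term


def oracle_evaluate(graph: TripleGraph, query: QuerySpec):
    """Nested-loop matcher: returns the same rows evaluate() must produce."""
    statements = list(graph)
    solutions = []

    def recurse(index, binding):
        if index == len(query.patterns):
            solutions.append(dict(binding))
            return
        pattern = query.patterns[index]
        want = (
            _ground(pattern.subject, binding),
            _ground(pattern.predicate, binding),
            _ground(pattern.object, binding),
        )
        for st in statements:
            actual = (st.subject, st.predicate, st.object)
            extended = dict(binding)
            ok = True
            for w, a in zip(want, actual):
                if is_variable(w):
                    if w in extended and extended[w] != a:
                        ok = False
                        break
                    extended[w] = a
                elif w != a:
                    ok = False
                    break
            if ok:
                recurse(index + 1, extended)

    recurse(0, {})

    def text_of(value):
        return value.lexical_form if isinstance(value, Literal) else str(value)

    kept = []
    for binding in solutions:
        ok = True
        for flt in query.filters:
            value = text_of(binding[flt.variable])
            if flt.operator == "equals":
                ok = value == flt.operand
            else:
                ok = re.search(flt.operand, value) is not None
            if not ok:
                break
        if ok:
            kept.append(binding)

    all_vars = set()
    for p in query.patterns:
        all_vars |= p.variables()
    projection = list(query.projection) or sorted(all_vars)
    rows = [tuple(b[v] for v in projection) for b in kept]
    if query.distinct:
        rows = list(set(rows))

    def key(row):
        return tuple(
            (1, v.lexical_form, v.datatype or "", v.language_tag or "")
            if isinstance(v, Literal)
            else (0, str(v), "", "")
            for v in row
        )

    rows.sort(key=key)
    if query.count:
        return [(Literal(str(len(rows))),)]
    return rows


def candidate_product(graph: TripleGraph, query: QuerySpec) -> int:
    """Upper bound on the oracle's work: product of per-pattern ground
    match counts (variables treated as wildcards)."""
    total = 1
    for pattern in query.patterns:
        count = 0
        for st in graph:
            if (
                (is_variable(pattern.subject) or pattern.subject == st.subject)
                and (is_variable(pattern.predicate) or pattern.predicate == st.predicate)
                and (is_variable(pattern.object) or pattern.object == st.object)
            ):
                count += 1
        total *= max(count, 1)
    return total
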