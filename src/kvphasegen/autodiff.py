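"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operator set the adversarial training loop needs
(affine layers, ReLU/sigmoid/softplus, reductions, elementwise algebra)
and — crucially — *double backprop*: backward passes are themselves built
from these operators, so gradient-norm penalties (R1, Wasserstein
gradient penalty) evaluated at real or interpolated samples can be
differentiated again with respect to the network weights.

Values are float64 throughout; graphs are built eagerly and freed with
the Python objects.  Not a general tensor library: broadcasting is
limited to what ``_unbroadcast`` can undo (trailing-dim and leading-dim
alignment as numpy defines it).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Var",
    "as_var",
    "vadd", "vsub", "vmul", "vdiv", "vneg", "vmatmul", "vtranspose",
    "vrelu", "vsigmoid", "vsoftplus", "vsquare", "vsqrt",
    "vsum", "vmean", "grad",
]


class Var:
    """A node in the computation graph: value + parents + pullback."""

    __slots__ = ("value", "parents", "grad_fn")

    def __init__(self, value, parents=(), grad_fn=None):
        self.value = np.asarray(value, dtype=np.float64)
        self.parents = parents
        self.grad_fn = grad_fn

    @property
    def shape(self):
        return self.value.shape

    def __repr__(self):
        return f"Var(shape={self.value.shape}, leaf={self.grad_fn is None})"

    # convenience operator sugar
    def __add__(self, other):
        return vadd(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return vsub(self, other)

    def __rsub__(self, other):
        return vsub(other, self)

    def __mul__(self, other):
        return vmul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return vdiv(self, other)

    def __neg__(self):
        return vneg(self)

    def __matmul__(self, other):
        return vmatmul(self, other)


def as_var(x) -> Var:
    return x if isinstance(x, Var) else Var(x)


def _unbroadcast(g: Var, shape: tuple) -> Var:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    # sum away leading extra axes
    while len(g.shape) > len(shape):
        g = vsum(g, axis=0)
    # sum broadcast (size-1) axes
    for ax, (gs, ss) in enumerate(zip(g.shape, shape)):
        if ss == 1 and gs != 1:
            g = vsum(g, axis=ax, keepdims=True)
    if g.shape != shape:
        g = vreshape(g, shape)
    return g


def vadd(a, b) -> Var:
    a, b = as_var(a), as_var(b)
    return Var(
        a.value + b.value,
        (a, b),
        lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)),
    )


def vsub(a, b) -> Var:
    a, b = as_var(a), as_var(b)
    return Var(
        a.value - b.value,
        (a, b),
        lambda g: (_unbroadcast(g, a.shape), _unbroadcast(vneg(g), b.shape)),
    )


def vneg(a) -> Var:
    a = as_var(a)
    return Var(-a.value, (a,), lambda g: (vneg(g),))


def vmul(a, b) -> Var:
    a, b = as_var(a), as_var(b)
    return Var(
        a.value * b.value,
        (a, b),
        lambda g: (_unbroadcast(vmul(g, b), a.shape), _unbroadcast(vmul(g, a), b.shape)),
    )


def vdiv(a, b) -> Var:
    a, b = as_var(a), as_var(b)
    out = Var(a.value / b.value, (a, b), None)
    out.grad_fn = lambda g: (
        _unbroadcast(vdiv(g, b), a.shape),
        _unbroadcast(vneg(vdiv(vmul(g, out), b)), b.shape),
    )
    return out


def vmatmul(a, b) -> Var:
    a, b = as_var(a), as_var(b)
    return Var(
        a.value @ b.value,
        (a, b),
        lambda g: (vmatmul(g, vtranspose(b)), vmatmul(vtranspose(a), g)),
    )


def vtranspose(a) -> Var:
    a = as_var(a)
    return Var(a.value.T, (a,), lambda g: (vtranspose(g),))


def vreshape(a, shape) -> Var:
    a = as_var(a)
    old = a.shape
    return Var(a.value.reshape(shape), (a,), lambda g: (vreshape(g, old),))


def vrelu(a) -> Var:
    a = as_var(a)
    mask = (a.value > 0).astype(np.float64)  # constant: d(relu)/dx a.e.
    return Var(a.value * mask, (a,), lambda g: (vmul(g, mask),))


def vsigmoid(a) -> Var:
    a = as_var(a)
    s = 1.0 / (1.0 + np.exp(-np.clip(a.value, -60, 60)))
    out = Var(s, (a,), None)
    out.grad_fn = lambda g: (vmul(g, vmul(out, vsub(1.0, out))),)
    return out


def vsoftplus(a) -> Var:
    """log(1 + exp(x)), numerically stable; derivative is sigmoid(x)."""
    a = as_var(a)
    val = np.logaddexp(0.0, a.value)
    return Var(val, (a,), lambda g: (vmul(g, vsigmoid(a)),))


def vsquare(a) -> Var:
    a = as_var(a)
    return Var(a.value**2, (a,), lambda g: (vmul(g, vmul(2.0, a)),))


def vsqrt(a) -> Var:
    a = as_var(a)
    out = Var(np.sqrt(a.value), (a,), None)
    out.grad_fn = lambda g: (vdiv(g, vmul(2.0, out)),)
    return out


def vsum(a, axis=None, keepdims=False) -> Var:
    a = as_var(a)
    val = a.value.sum(axis=axis, keepdims=keepdims)
    shape = a.shape

    def gf(g):
        gv = g
        if axis is not None and not keepdims:
            expanded = list(val.shape)
            ax = axis if axis >= 0 else len(shape) + axis
            expanded.insert(ax, 1)
            gv = vreshape(gv, tuple(expanded))
        return (vbroadcast(gv, shape),)

    return Var(val, (a,), gf)


def vbroadcast(a, shape) -> Var:
    a = as_var(a)
    return Var(
        np.broadcast_to(a.value, shape).copy(),
        (a,),
        lambda g: (_unbroadcast(g, a.shape),),
    )


def vmean(a, axis=None, keepdims=False) -> Var:
    a = as_var(a)
    n = a.value.size if axis is None else a.shape[axis]
    return vmul(vsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def _topo(root: Var) -> list[Var]:
    order: list[Var] = []
    seen: set[int] = set()
    stack = [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            if id(p) not in seen:
                stack.append((p, False))
    return order


def grad(output: Var, wrt: list[Var], grad_output=None) -> list[Var]:
    """Gradients of ``output`` w.r.t. ``wrt`` leaves.

    The returned gradients are :class:`Var` nodes whose own graphs reach
    back to every leaf ``output`` depends on, so they can be fed to
    :func:`grad` again (double backprop).  Leaves that ``output`` does not
    depend on get zero gradients.
    """
    if grad_output is None:
        grad_output = Var(np.ones_like(output.value))
    grads: dict[int, Var] = {id(output): as_var(grad_output)}
    for node in reversed(_topo(output)):
        g = grads.get(id(node))
        if g is None or node.grad_fn is None:
            continue
        parent_grads = node.grad_fn(g)
        for p, pg in zip(node.parents, parent_grads):
            if pg is None:
                continue
            cur = grads.get(id(p))
            grads[id(p)] = pg if cur is None else vadd(cur, pg)
    return [
        grads.get(id(w), Var(np.zeros_like(w.value))) for w in wrt
    ]
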