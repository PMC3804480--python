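"""Arithmetic mini-language for config-file kernel and field expressions.

Grammar (a strict subset of Python expression syntax, parsed via ``ast``):
numbers, the variables ``u``, ``u1``, ``u2``, the constants ``pi`` and
``e``, the operators ``+ - * / **``, unary ``+ -``, parentheses, and the
functions ``sin cos tan exp log sqrt abs tanh``.  Everything else is
rejected, so config files cannot execute arbitrary code.  Expressions are
evaluated vectorized over numpy arrays.
"""

from __future__ import annotations

import ast
from typing import Callable

import numpy as np

from .errors import ConfigError

_FUNCS = {
    "sin": np.sin,
    "cos": np.cos,
    "tan": np.tan,
    "exp": np.exp,
    "log": np.log,
    "sqrt": np.sqrt,
    "abs": np.abs,
    "tanh": np.tanh,
}
_CONSTS = {"pi": np.pi, "e": np.e}
_BINOPS = (ast.Add, ast.Sub, ast.Mult, ast.Div, ast.Pow)
_UNARYOPS = (ast.UAdd, ast.USub)


def _check(node: ast.AST, variables: tuple[str, ...], path: str) -> None:
    if isinstance(node, ast.Expression):
        _check(node.body, variables, path)
    elif isinstance(node, ast.BinOp) and isinstance(node.op, _BINOPS):
        _check(node.left, variables, path)
        _check(node.right, variables, path)
    elif isinstance(node, ast.UnaryOp) and isinstance(node.op, _UNARYOPS):
        _check(node.operand, variables, path)
    elif isinstance(node, ast.Constant) and isinstance(node.value, (int, float)):
        pass
    elif isinstance(node, ast.Name):
        if node.id not in variables and node.id not in _CONSTS:
            raise ConfigError(
                "parse-error", path, f"unknown name {node.id!r} in expression"
            )
    elif isinstance(node, ast.Call):
        if not (isinstance(node.func, ast.Name) and node.func.id in _FUNCS):
            raise ConfigError("parse-error", path, "only whitelisted functions allowed")
        if node.keywords or len(node.args) != 1:
            raise ConfigError("parse-error", path, "functions take one argument")
        _check(node.args[0], variables, path)
    else:
        raise ConfigError(
            "parse-error", path, f"disallowed syntax {type(node).__name__}"
        )


def compile_expression(
    src: str, variables: tuple[str, ...], path: str = "<expr>"
) -> Callable[..., np.ndarray]:
    """Compile ``src`` into a vectorized function of the named variables."""
    try:
        tree = ast.parse(src, mode="eval")
    except SyntaxError as exc:
        raise ConfigError("parse-error", path, str(exc)) from None
    _check(tree, variables, path)
    code = compile(tree, filename=f"<{path}>", mode="eval")
    env = {"__builtins__": {}} | _FUNCS | _CONSTS

    def fn(**kwargs):
        local = {k: np.asarray(v, dtype=float) for k, v in kwargs.items()}
        return np.asarray(eval(code, env, local), dtype=float)

    return fn
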