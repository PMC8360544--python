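"""Cost transfer between settings: market-basket index, PPP, inflation.

Costs sourced from UK and US studies are expressed at the South African
price level in 2020 international dollars via three multiplicative
steps, applied in a configurable order (default: inflate in the source
currency to 2020, convert to international dollars by a purchasing-power
-parity factor, then divide by the source-to-South-Africa market-basket
index).

The market-basket index is the ratio of the total cost of a fixed basket
of healthcare goods and services between two settings; the published
totals give a UK-South Africa index of 8,759 / 4,519 = 1.94 and a
USA-South Africa index of 10.8.

The decision model itself consumes the published *adjusted* cost values
directly (the published adjusted column is not reproducible row-by-row
from the printed factors); this module is a supporting, auditable
utility validated against the basket index and the pneumonia-episode
row.  Rand figures are display-only, produced by a single configurable
$-to-R factor (default 17.35, fitted to the published $/R pairs; note
the source's own small-value $/R pairs imply a different factor, see
docs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import yaml

from .parameters import CostItem, ValidationError

DEFAULT_ZAR_PER_INTL_USD = 17.35


@dataclass(frozen=True)
class Basket:
    """A fixed basket of healthcare goods/services priced in one setting."""

    setting: str
    items: tuple[tuple[str, float], ...]
    total: float | None = None

    def __post_init__(self):
        if not self.items:
            raise ValidationError("items", "basket must contain at least one item")
        s = sum(cost for _, cost in self.items)
        if self.total is None:
            object.__setattr__(self, "total", s)
        elif abs(self.total - s) > 0.5:
            raise ValidationError("total", f"total {self.total} != item sum {s}")


def basket_index(source: Basket, target: Basket) -> float:
    """Source-per-target basket cost ratio (full precision; print at 2 dp)."""
    if source.total <= 0 or target.total <= 0:
        raise ValidationError("total", "basket totals must be positive")
    return source.total / target.total


@dataclass(frozen=True)
class ConversionContext:
    """Factors needed to move a cost to 2020 international dollars.

    ``basket_index`` maps a source setting to its setting-to-South-Africa
    index (a bare float is accepted for single-setting use).
    ``inflation`` maps currency -> year -> annual factor and must cover
    every year after the source year through 2020.
    """

    basket_index: Mapping[str, float] | float
    ppp_per_intl_usd: Mapping[str, float] = field(default_factory=lambda: {"USD": 1.0})
    inflation: Mapping[str, Mapping[int, float]] = field(default_factory=dict)
    display_zar_per_intl_usd: float = DEFAULT_ZAR_PER_INTL_USD
    order: tuple[str, ...] = ("inflate", "ppp", "basket")
    target_year: int = 2020

    def index_for(self, setting: str | None) -> float:
        if isinstance(self.basket_index, Mapping):
            if setting not in self.basket_index:
                raise ValidationError("basket_index", f"no index for setting {setting!r}")
            return float(self.basket_index[setting])
        return float(self.basket_index)


@dataclass(frozen=True)
class ConversionResult:
    value: float
    chain: tuple[str, ...]  # per-step audit trail


def _inflation_factor(ctx: ConversionContext, currency: str, year: int) -> float:
    series = ctx.inflation.get(currency, {})
    factor = 1.0
    for y in range(year + 1, ctx.target_year + 1):
        if y not in series:
            raise ValidationError(
                "inflation", f"no {currency} factor for year {y} (source year {year})")
        factor *= series[y]
    return factor


def adjust_cost(item: CostItem, ctx: ConversionContext,
                setting: str | None = None) -> ConversionResult:
    """Express a raw source-currency cost in 2020 international dollars.

    The step order comes from ``ctx.order``; each applied step is logged
    in the returned chain for per-item audit.
    """
    if item.raw_value is None or item.source_currency is None or item.source_year is None:
        raise ValidationError(item.name, "raw value, currency and year required")
    value = float(item.raw_value)
    chain = [f"start {value:.4f} {item.source_currency} ({item.source_year})"]
    for step in ctx.order:
        if step == "inflate":
            f = _inflation_factor(ctx, item.source_currency, item.source_year)
            value *= f
            chain.append(f"inflate to {ctx.target_year} x{f:.4f} -> {value:.4f}")
        elif step == "ppp":
            ppp = ctx.ppp_per_intl_usd.get(item.source_currency)
            if ppp is None or ppp <= 0:
                raise ValidationError("ppp", f"no PPP factor for {item.source_currency}")
            value /= ppp
            chain.append(f"ppp /{ppp:.4f} -> {value:.4f} intl$")
        elif step == "basket":
            idx = ctx.index_for(setting if setting is not None
                                else (item.setting or "USA"))
            value /= idx
            chain.append(f"basket index /{idx:.4f} -> {value:.4f}")
        else:
            raise ValidationError("order", f"unknown conversion step {step!r}")
    return ConversionResult(value, tuple(chain))


def to_display_zar(value: float,
                   factor: float = DEFAULT_ZAR_PER_INTL_USD) -> float:
    """International dollars to display South African Rand."""
    return value * factor


def load_conversion_context(source=None) -> tuple[dict[str, Basket], ConversionContext]:
    """Bundled baskets and conversion context (editable YAML fixture)."""
    if source is None:
        source = resources.files("mouthwash_cea.data").joinpath("conversion.yaml").open()
    cfg = yaml.safe_load(source.read() if hasattr(source, "read") else open(source).read())
    baskets = {
        key: Basket(spec["setting"], tuple((n, float(c)) for n, c in spec["items"]))
        for key, spec in cfg["baskets"].items()
    }
    ctx = ConversionContext(
        basket_index=cfg["basket_indices"],
        ppp_per_intl_usd=cfg["ppp_per_intl_usd"],
        inflation={cur: {int(y): float(f) for y, f in series.items()}
                   for cur, series in cfg["inflation"].items()},
        display_zar_per_intl_usd=float(cfg.get("display_zar_per_intl_usd",
                                               DEFAULT_ZAR_PER_INTL_USD)),
        order=tuple(cfg.get("order", ("inflate", "ppp", "basket"))),
    )
    return baskets, ctx
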