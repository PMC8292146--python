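"""Reading and writing ASAP XML annotations (dots, polygons, point sets).

ASAP (Automated Slide Analysis Platform) stores annotations as::

    <ASAP_Annotations>
      <Annotations>
        <Annotation Name="..." Type="Dot|Polygon|PointSet" PartOfGroup="...">
          <Coordinates>
            <Coordinate Order="0" X="..." Y="..."/>
          </Coordinates>
        </Annotation>
      </Annotations>
      <AnnotationGroups>
        <Group Name="..." PartOfGroup="None" Color="#64FE2E"/>
      </AnnotationGroups>
    </ASAP_Annotations>

Coordinates are global pixel coordinates.  Dot annotations are single points
labelled by their group (the marker); polygons are ROI inclusions/exclusions;
point sets encode polylines such as the renal capsule.
"""

from __future__ import annotations

from dataclasses import dataclass

from lxml import etree


@dataclass(frozen=True)
class DotAnnotation:
    """A ground-truth dot: global pixel coordinates plus marker label."""

    x: float
    y: float
    marker: str = ""


@dataclass
class AsapAnnotation:
    name: str
    atype: str  # "Dot", "Polygon", "PointSet"
    group: str
    coordinates: list[tuple[float, float]]


def write_asap_xml(path, annotations: list[AsapAnnotation]) -> None:
    root = etree.Element("ASAP_Annotations")
    anns = etree.SubElement(root, "Annotations")
    groups: dict[str, None] = {}
    for a in annotations:
        el = etree.SubElement(
            anns, "Annotation",
            Name=a.name, Type=a.atype, PartOfGroup=a.group or "None", Color="#F4FA58",
        )
        coords = etree.SubElement(el, "Coordinates")
        for i, (x, y) in enumerate(a.coordinates):
            etree.SubElement(coords, "Coordinate", Order=str(i), X=repr(float(x)), Y=repr(float(y)))
        if a.group:
            groups[a.group] = None
    groups_el = etree.SubElement(root, "AnnotationGroups")
    for g in groups:
        etree.SubElement(groups_el, "Group", Name=g, PartOfGroup="None", Color="#64FE2E")
    etree.ElementTree(root).write(str(path), pretty_print=True, xml_declaration=True, encoding="utf-8")


def read_asap_xml(path) -> list[AsapAnnotation]:
    tree = etree.parse(str(path))
    out = []
    for el in tree.findall(".//Annotations/Annotation"):
        coords = [
            (float(c.get("X")), float(c.get("Y")))
            for c in sorted(el.findall("Coordinates/Coordinate"), key=lambda c: int(c.get("Order")))
        ]
        out.append(
            AsapAnnotation(
                name=el.get("Name", ""),
                atype=el.get("Type", "Dot"),
                group=el.get("PartOfGroup", "None"),
                coordinates=coords,
            )
        )
    return out


def read_dots(path) -> list[DotAnnotation]:
    """Read all Dot annotations as :class:`DotAnnotation` (marker = group)."""
    dots = []
    for a in read_asap_xml(path):
        if a.atype == "Dot" and a.coordinates:
            x, y = a.coordinates[0]
            dots.append(DotAnnotation(x=x, y=y, marker=a.group if a.group != "None" else ""))
    return dots


def write_dots(path, dots: list[DotAnnotation]) -> None:
    anns = [
        AsapAnnotation(name=f"dot_{i}", atype="Dot", group=d.marker or "None", coordinates=[(d.x, d.y)])
        for i, d in enumerate(dots)
    ]
    write_asap_xml(path, anns)
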