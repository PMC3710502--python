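<!-- Dataset file, XML dialect (canonical writer output). -->
<!ELEMENT dataset (name, chain, points)>
<!ELEMENT name (#PCDATA)>
<!ELEMENT chain (#PCDATA)>
<!ELEMENT points (point+)>
<!ELEMENT point (x, y, z)>
<!ELEMENT x (#PCDATA)>
<!ELEMENT y (#PCDATA)>
<!ELEMENT z (#PCDATA)>
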