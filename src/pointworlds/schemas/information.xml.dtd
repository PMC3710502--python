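<!-- Information-layer file, XML dialect (canonical writer output). -->
<!ELEMENT information (set+)>
<!ELEMENT set (name?, numClass, labels?, values)>
<!ELEMENT name (#PCDATA)>
<!ELEMENT numClass (#PCDATA)>
<!ELEMENT labels (label*)>
<!ELEMENT label (#PCDATA)>
<!ELEMENT values (value+)>
<!ELEMENT value (#PCDATA)>
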