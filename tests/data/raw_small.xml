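<?xml version='1.0' encoding='UTF-8'?>
<corpus>
  <post forum="bodyforum" thread="supplementen" id="r001" index="0" author="user013" timestamp="2016-04-01T08:00:00">
    <title>caf&amp;eacute;ine stack</title>
    <body>Vandaag   mijn eerste dag met de nieuwe stack.

Het caf&amp;eacute;ine gehalte is    flink hoger dan verwacht.


Iemand hier ervaring mee?</body>
  </post>
</corpus>
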