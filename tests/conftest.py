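import pathlib
import sys

# make the shared oracle helpers importable regardless of invocation style
sys.path.insert(0, str(pathlib.Path(__file__).parent))
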